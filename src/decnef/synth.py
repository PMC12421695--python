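"""Synthetic ROI time series and heartbeat-counting behaviour.

The generator emulates the signal structure the analysis assumes: two
condition-specific multivoxel activation patterns (weak, sub-percent
per-voxel amplitudes so that single-trial decoding sits in the near-chance
regime the feedback task operates in) expressed as HRF-convolved 10-s
boxcars on top of a constant baseline, AR(1)-plus-white noise at ~1% of
baseline, a slow sinusoidal drift, run-level engagement variability, and —
only for subjects receiving contingent feedback — a per-subject
learnability parameter that grows the pattern amplitude over regulation
runs.
Behavioural heartbeat-counting sessions are coupled to the regulation
learning effect through a single gain parameter.

Every draw is reproducible: per-subject and per-run streams are derived
from one cohort seed via ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .mvpa import canonical_hrf
from .schedule import AcquisitionParams, Condition, RunKind, RunSchedule, build_schedule

HEARTBEAT_DURATIONS = (15, 25, 35, 45, 55, 65)


@dataclass
class SubjectParams:
    """Ground-truth generative parameters of one simulated participant."""

    subject_id: str
    group: Literal["NF", "Sham"]
    learnability: float  # lambda: fractional pattern-amplitude growth per run
    pattern_intero: np.ndarray  # voxel amplitudes, % of baseline
    pattern_extero: np.ndarray
    noise_sd: float = 1.0  # stationary AR(1) sd, % units
    ar1_rho: float = 0.3
    drift_amplitude: float = 0.5  # % units
    baseline_level: float = 1000.0
    heart_rate_pre: float = 72.0  # beats/min
    heart_rate_post: float = 67.0
    perception_fraction_pre: float = 0.55
    behaviour_coupling: float = 0.8  # alpha: gain from CA learning effect
    confidence_pre: float = 50.0
    run_amplitude_sd: float = 0.35  # run-to-run engagement variability

    def __post_init__(self) -> None:
        self.pattern_intero = np.asarray(self.pattern_intero, dtype=float)
        self.pattern_extero = np.asarray(self.pattern_extero, dtype=float)
        if self.learnability < 0:
            raise ValueError("learnability must be >= 0")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.perception_fraction_pre <= 1:
            raise ValueError("perception_fraction_pre must be in [0, 1]")


@dataclass
class RoiTimeSeries:
    """Raw-signal volumes x voxels matrix plus its acquisition context."""

    data: np.ndarray
    params: AcquisitionParams
    schedule: RunSchedule

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != self.schedule.n_volumes:
            raise ValueError("row count must equal schedule.n_volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")


@dataclass
class HeartbeatTrial:
    """One heartbeat-counting trial of the pre/post behavioural task."""

    duration_seconds: int
    recorded_beats: int
    reported_beats: int
    confidence: float = 50.0

    def __post_init__(self) -> None:
        if self.duration_seconds not in HEARTBEAT_DURATIONS:
            raise ValueError(f"duration must be one of {HEARTBEAT_DURATIONS}")
        if self.recorded_beats <= 0:
            raise ValueError("recorded_beats must be positive")
        if self.reported_beats < 0:
            raise ValueError("reported_beats must be >= 0")


@dataclass
class SimulatedSubject:
    """All simulated data of one participant: 4 runs + behavioural sessions."""

    params: SubjectParams
    runs: List[RoiTimeSeries]
    seed: int
    heartbeat_pre: List[HeartbeatTrial] = field(default_factory=list)
    heartbeat_post: List[HeartbeatTrial] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.runs) != 4:
            raise ValueError("a subject has exactly 4 runs (task + 3 regulation)")


@dataclass
class PopulationConfig:
    """Cohort-level distributions from which subjects are drawn.

    The learnability mixture assigns a fraction of contingent-feedback
    subjects a near-zero lambda ("non-learners", reflecting the roughly
    40% neurofeedback-inefficiency prevalence); learners draw lambda from
    a truncated normal.  Pattern vectors are i.i.d. normal per voxel with
    ``pattern_sd`` percent amplitude.
    """

    nonlearner_fraction: float = 0.4
    learner_lambda_mean: float = 1.0
    learner_lambda_sd: float = 0.3
    pattern_sd: float = 0.02  # per-voxel pattern amplitude sd, % units
    run_amplitude_sd: float = 0.35
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 0.5
    baseline_level: float = 1000.0
    heart_rate_pre_mean: float = 73.0
    heart_rate_pre_sd: float = 9.0
    heart_rate_drop_mean: float = 6.0
    heart_rate_drop_sd: float = 3.0
    perception_fraction_mean: float = 0.55
    perception_fraction_sd: float = 0.15
    perception_jitter_sd: float = 0.11  # per-session state variability
    behaviour_coupling: float = 0.8
    report_noise_sd: float = 1.5  # integer beats added to each report


def _effective_patterns(
    subject: SubjectParams, run_index: int, state_factor: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pattern vectors for a run, with learnability growth for NF subjects.

    Amplitude scale is 1 + lambda * run_index for contingent-feedback
    subjects (run 0 is the decoder-training task, scale 1); non-contingent
    subjects keep scale 1 in every run.  ``state_factor`` models run-level
    engagement fluctuations common to both conditions.
    """
    scale = 1.0 + subject.learnability * run_index if subject.group == "NF" else 1.0
    scale *= state_factor
    return subject.pattern_intero * scale, subject.pattern_extero * scale


def simulate_run(
    schedule: RunSchedule,
    subject: SubjectParams,
    run_index: int,
    seed: int | np.random.SeedSequence,
    params: Optional[AcquisitionParams] = None,
) -> RoiTimeSeries:
    """Simulate one run's raw ROI signal.

    signal(t, v) = baseline * (1 + s(t, v)/100) + AR(1) noise + drift,
    where s is the HRF-convolved condition boxcar times the (possibly
    learnability-scaled) pattern vector.
    """
    if params is None:
        params = AcquisitionParams(n_voxels=len(subject.pattern_intero))
    n_vol, n_vox = schedule.n_volumes, len(subject.pattern_intero)
    rng = np.random.default_rng(seed)
    tr = params.tr_seconds
    grid = np.arange(n_vol) * tr

    box = {c: np.zeros(n_vol) for c in Condition}
    for block in schedule.blocks:
        on, off = block.regulation_onset_seconds, block.regulation_offset_seconds
        box[block.condition][(grid >= on - 1e-9) & (grid < off - 1e-9)] = 1.0
    hrf = canonical_hrf(tr)
    reg = {c: np.convolve(box[c], hrf)[:n_vol] for c in Condition}

    state = max(0.0, 1.0 + rng.normal(0.0, subject.run_amplitude_sd))
    p_int, p_ext = _effective_patterns(subject, run_index, state)
    s = np.outer(reg[Condition.INTEROCEPTIVE], p_int) + np.outer(
        reg[Condition.EXTEROCEPTIVE], p_ext
    )

    unit = subject.baseline_level / 100.0  # 1% of baseline in raw units
    innov_sd = subject.noise_sd * np.sqrt(1.0 - subject.ar1_rho**2)
    noise = lfilter([1.0], [1.0, -subject.ar1_rho], rng.standard_normal((n_vol, n_vox)), axis=0)
    noise *= innov_sd * unit
    phase = rng.uniform(0, 2 * np.pi, size=n_vox)
    drift = subject.drift_amplitude * unit * np.sin(
        2 * np.pi * grid[:, None] / 128.0 + phase[None, :]
    )

    data = subject.baseline_level * (1.0 + s / 100.0) + noise + drift
    return RoiTimeSeries(data=data, params=params, schedule=schedule)


def simulate_subject_runs(
    subject: SubjectParams,
    seed: int | np.random.SeedSequence,
    params: Optional[AcquisitionParams] = None,
) -> List[RoiTimeSeries]:
    """Decoder-training run plus three regulation runs for one subject."""
    if params is None:
        params = AcquisitionParams(n_voxels=len(subject.pattern_intero))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    run_seeds = ss.spawn(4)
    runs = [
        simulate_run(
            build_schedule(RunKind.DECODER_TRAINING, params, 0), subject, 0, run_seeds[0], params
        )
    ]
    for r in (1, 2, 3):
        runs.append(
            simulate_run(
                build_schedule(RunKind.REGULATION, params, r), subject, r, run_seeds[r], params
            )
        )
    return runs


def simulate_heartbeat_session(
    subject: SubjectParams,
    session: Literal["pre", "post"],
    learning_effect: float,
    seed: int | np.random.SeedSequence,
    *,
    perception_jitter_sd: float = 0.11,
    report_noise_sd: float = 1.5,
) -> List[HeartbeatTrial]:
    """Six heartbeat-counting trials, one per duration.

    Recorded beats follow the session's heart rate with small jitter; the
    reported count is the recorded count scaled by the subject's effective
    perception fraction — raised by ``behaviour_coupling x learning_effect``
    for contingent-feedback subjects after training — plus integer noise.
    """
    if session == "pre" and learning_effect != 0:
        raise ValueError("learning_effect must be 0 for the pre session")
    rng = np.random.default_rng(seed)
    rate = subject.heart_rate_pre if session == "pre" else subject.heart_rate_post
    gain = subject.behaviour_coupling * learning_effect if subject.group == "NF" else 0.0
    fraction = float(
        np.clip(subject.perception_fraction_pre + gain + rng.normal(0, perception_jitter_sd), 0, 1)
    )
    trials = []
    for dur in HEARTBEAT_DURATIONS:
        recorded = max(1, int(round(rate * dur / 60.0 + rng.normal(0, 1.0))))
        reported = int(round(recorded * fraction + rng.normal(0, report_noise_sd)))
        trials.append(
            HeartbeatTrial(
                duration_seconds=dur,
                recorded_beats=recorded,
                reported_beats=max(0, reported),
                confidence=float(np.clip(subject.confidence_pre + rng.normal(0, 5), 0, 100)),
            )
        )
    return trials


def draw_subject_params(
    subject_id: str,
    group: Literal["NF", "Sham"],
    config: PopulationConfig,
    n_voxels: int,
    rng: np.random.Generator,
) -> SubjectParams:
    """Draw one subject's generative parameters from the population."""
    if rng.random() < config.nonlearner_fraction:
        lam = 0.0
    else:
        lam = max(0.0, rng.normal(config.learner_lambda_mean, config.learner_lambda_sd))
    hr_pre = rng.normal(config.heart_rate_pre_mean, config.heart_rate_pre_sd)
    hr_post = hr_pre - rng.normal(config.heart_rate_drop_mean, config.heart_rate_drop_sd)
    return SubjectParams(
        subject_id=subject_id,
        group=group,
        learnability=lam,
        pattern_intero=rng.normal(0, config.pattern_sd, size=n_voxels),
        pattern_extero=rng.normal(0, config.pattern_sd, size=n_voxels),
        noise_sd=config.noise_sd,
        ar1_rho=config.ar1_rho,
        drift_amplitude=config.drift_amplitude,
        baseline_level=config.baseline_level,
        heart_rate_pre=float(np.clip(hr_pre, 40, 140)),
        heart_rate_post=float(np.clip(hr_post, 40, 140)),
        perception_fraction_pre=float(
            np.clip(rng.normal(config.perception_fraction_mean, config.perception_fraction_sd), 0, 1)
        ),
        behaviour_coupling=config.behaviour_coupling,
        confidence_pre=float(np.clip(rng.normal(50, 15), 0, 100)),
        run_amplitude_sd=config.run_amplitude_sd,
    )


def simulate_cohort(
    n_nf: int = 28,
    n_sham: int = 26,
    population_config: Optional[PopulationConfig] = None,
    seed: int = 0,
    params: Optional[AcquisitionParams] = None,
    simulate_behaviour: bool = False,
) -> List[SimulatedSubject]:
    """Draw a full cohort of simulated subjects, NF arm first.

    Behavioural sessions depend on each subject's realised learning effect
    and are therefore normally attached later by the closed-loop driver;
    ``simulate_behaviour`` adds pre-sessions only (post requires feedback).
    """
    if n_nf < 0 or n_sham < 0:
        raise ValueError("cohort sizes must be >= 0")
    if population_config is None:
        population_config = PopulationConfig()
    if params is None:
        params = AcquisitionParams()
    ss = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = ss.spawn(n_nf + n_sham)

    subjects = []
    labels = [("NF", i) for i in range(n_nf)] + [("Sham", i) for i in range(n_sham)]
    for (group, i), sub_ss in zip(labels, subject_seeds):
        sid = f"{group.lower()}{i + 1:02d}"
        sp = draw_subject_params(sid, group, population_config, params.n_voxels, draw_rng)
        run_ss, beh_ss = sub_ss.spawn(2)
        runs = simulate_subject_runs(sp, run_ss, params)
        subj = SimulatedSubject(params=sp, runs=runs, seed=seed)
        if simulate_behaviour:
            subj.heartbeat_pre = simulate_heartbeat_session(
                sp,
                "pre",
                0.0,
                beh_ss,
                perception_jitter_sd=population_config.perception_jitter_sd,
                report_noise_sd=population_config.report_noise_sd,
            )
        subjects.append(subj)
    return subjects
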