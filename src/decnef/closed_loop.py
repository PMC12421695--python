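"""End-to-end simulated neurofeedback experiment.

Per subject: decoder-training features -> per-run incremental decoder
retraining -> per-trial Platt-calibrated feedback.  Contingent-feedback
subjects see their true scores; sham subjects see statistically matched
scores drawn from a generator fitted on the contingent arm, while their
true scores are still computed (but never displayed) for validation.
Behavioural heartbeat-counting sessions are simulated before training and
after it, with the post-session perception gain coupled to the displayed
classification-accuracy learning effect for the contingent arm only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .behaviour import (
    SubjectOutcome,
    bpm_summary,
    group_statistics,
    interoceptive_accuracy,
    mean_confidence,
)
from .decoder import train_run_decoder
from .feedback import (
    FeedbackRecord,
    RunSummary,
    learning_effects_from_summaries,
    summarise_run,
    summarise_scores,
    trial_feedback,
)
from .preprocess import extract_trial_features, psc_from_run
from .schedule import AcquisitionParams
from .sham import ShamScoreGenerator
from .synth import (
    PopulationConfig,
    SimulatedSubject,
    simulate_cohort,
    simulate_heartbeat_session,
)
from .mvpa import run_offline_cv


@dataclass
class ExperimentConfig:
    """Everything needed to run the simulated experiment end to end."""

    n_nf: int = 28
    n_sham: int = 26
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    hemodynamic_shift: int = 2
    c_param: float = 1.0
    sham_bin_width: float = 10.0
    estimate_sham_rates: bool = True
    sham_transition_on: str = "bins"
    compute_mvpa: bool = True
    simulate_behaviour: bool = True

    @classmethod
    def from_dict(cls, d: Dict) -> "ExperimentConfig":
        d = dict(d)
        if "acquisition" in d:
            d["acquisition"] = AcquisitionParams(**d["acquisition"])
        if "population" in d:
            d["population"] = PopulationConfig(**d["population"])
        return cls(**d)


@dataclass
class SessionResult:
    """Complete per-subject result bundle of one simulated session."""

    subject_id: str
    group: str
    displayed_summaries: List[RunSummary]
    true_summaries: List[RunSummary]
    records: List[FeedbackRecord]
    displayed_scores: np.ndarray  # 3 x 24
    true_scores: np.ndarray  # 3 x 24
    offline_ca: Dict[int, float]
    outcome: Optional[SubjectOutcome] = None


def run_subject_session(
    subject: SimulatedSubject,
    sham_model: Optional[ShamScoreGenerator],
    config: Optional[ExperimentConfig] = None,
    seed: int | np.random.SeedSequence = 0,
) -> SessionResult:
    """Execute the feedback loop for one simulated subject.

    ``sham_model`` is required for (and only used by) sham-group subjects;
    ``seed`` drives the sham draw and behavioural simulation only — the
    brain data are fixed inside ``subject``.
    """
    if config is None:
        config = ExperimentConfig()
    group = subject.params.group
    if group == "Sham" and sham_model is None:
        raise ValueError("sham-group subjects require a fitted sham model")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sham_ss, beh_pre_ss, beh_post_ss = ss.spawn(3)

    params = config.acquisition
    history = {}
    psc0 = psc_from_run(subject.runs[0].data, subject.runs[0].schedule, params)
    history[0] = extract_trial_features(
        psc0, subject.runs[0].schedule, params, shift=config.hemodynamic_shift
    )

    records: List[FeedbackRecord] = []
    true_summaries: List[RunSummary] = []
    true_scores = np.empty((3, 24))
    for r in (1, 2, 3):
        model = train_run_decoder(history, r, c_param=config.c_param)
        run = subject.runs[r]
        psc = psc_from_run(run.data, run.schedule, params)
        feats = extract_trial_features(psc, run.schedule, params, shift=config.hemodynamic_shift)
        run_records = [trial_feedback(model, f) for f in feats]
        records.extend(run_records)
        true_summaries.append(summarise_run(run_records))
        true_scores[r - 1] = [rec.score for rec in run_records]
        history[r] = feats

    if group == "Sham":
        displayed_scores = sham_model.sample_session(np.random.default_rng(sham_ss))
        displayed_summaries = [
            summarise_scores(r + 1, displayed_scores[r], subject.runs[r + 1].schedule.conditions())
            for r in range(3)
        ]
    else:
        displayed_scores = true_scores.copy()
        displayed_summaries = true_summaries

    offline_ca: Dict[int, float] = {}
    if config.compute_mvpa:
        for r in range(4):
            run = subject.runs[r]
            psc = psc_from_run(run.data, run.schedule, params)
            offline_ca[r] = run_offline_cv(psc, run.schedule, params)

    outcome = None
    if config.simulate_behaviour:
        les = learning_effects_from_summaries(displayed_summaries)
        pop = config.population
        pre = subject.heartbeat_pre or simulate_heartbeat_session(
            subject.params,
            "pre",
            0.0,
            beh_pre_ss,
            perception_jitter_sd=pop.perception_jitter_sd,
            report_noise_sd=pop.report_noise_sd,
        )
        post = simulate_heartbeat_session(
            subject.params,
            "post",
            les["le_ca"],
            beh_post_ss,
            perception_jitter_sd=pop.perception_jitter_sd,
            report_noise_sd=pop.report_noise_sd,
        )
        subject.heartbeat_pre, subject.heartbeat_post = list(pre), list(post)
        bpm_a_pre, bpm_p_pre = bpm_summary(pre)
        bpm_a_post, bpm_p_post = bpm_summary(post)
        outcome = SubjectOutcome(
            subject_id=subject.params.subject_id,
            group=group,
            ia_pre=interoceptive_accuracy(pre),
            ia_post=interoceptive_accuracy(post),
            confidence_pre=mean_confidence(pre),
            confidence_post=mean_confidence(post),
            le_score=les["le_score"],
            le_ca=les["le_ca"],
            bpm_actual_pre=bpm_a_pre,
            bpm_actual_post=bpm_a_post,
            bpm_perceived_pre=bpm_p_pre,
            bpm_perceived_post=bpm_p_post,
        )

    return SessionResult(
        subject_id=subject.params.subject_id,
        group=group,
        displayed_summaries=displayed_summaries,
        true_summaries=true_summaries,
        records=records,
        displayed_scores=displayed_scores,
        true_scores=true_scores,
        offline_ca=offline_ca,
        outcome=outcome,
    )


def run_cohort_experiment(
    config: Optional[ExperimentConfig] = None, seed: int = 0
) -> Dict:
    """Simulate the full cohort and aggregate the group-level report.

    The contingent arm is run first; its displayed scores fit the sham
    generator, which then drives the sham arm's displayed feedback.  The
    report bundles per-subject outcomes, group statistics, offline MVPA
    means and the sham validation diagnostics, and is fully reproducible
    from ``seed``.
    """
    if config is None:
        config = ExperimentConfig()
    ss = np.random.SeedSequence(seed)
    cohort_ss, session_ss = ss.spawn(2)
    subjects = simulate_cohort(
        config.n_nf,
        config.n_sham,
        config.population,
        seed=int(cohort_ss.generate_state(1)[0] % (2**31)),
        params=config.acquisition,
    )
    session_seeds = session_ss.spawn(len(subjects))

    nf_subjects = [s for s in subjects if s.params.group == "NF"]
    sham_subjects = [s for s in subjects if s.params.group == "Sham"]
    nf_seeds = session_seeds[: len(nf_subjects)]
    sham_seeds = session_seeds[len(nf_subjects) :]

    results: List[SessionResult] = []
    for subj, s in zip(nf_subjects, nf_seeds):
        results.append(run_subject_session(subj, None, config, s))

    sham_model = None
    if sham_subjects:
        if nf_subjects:
            scores_by_run = [
                np.concatenate([res.displayed_scores[r] for res in results]) for r in range(3)
            ]
        else:  # no contingent arm to match: fall back to a flat score pool
            scores_by_run = [np.linspace(0.5, 99.5, 100)] * 3
        sham_model = ShamScoreGenerator(
            bin_width=config.sham_bin_width,
            estimate_rates=config.estimate_sham_rates and bool(nf_subjects),
            transition_on=config.sham_transition_on,
        ).fit(scores_by_run)
        for subj, s in zip(sham_subjects, sham_seeds):
            results.append(run_subject_session(subj, sham_model, config, s))

    report: Dict = {
        "seed": seed,
        "n_subjects": len(results),
        "subjects": [
            {
                "subject_id": res.subject_id,
                "group": res.group,
                "displayed": [s.to_dict() for s in res.displayed_summaries],
                "true": [s.to_dict() for s in res.true_summaries],
                "offline_ca": {str(k): v for k, v in res.offline_ca.items()},
                "outcome": res.outcome.to_dict() if res.outcome else None,
            }
            for res in results
        ],
    }

    if config.simulate_behaviour:
        outcomes: Dict[str, List[SubjectOutcome]] = {}
        for res in results:
            outcomes.setdefault(res.group, []).append(res.outcome)
        report["group_statistics"] = group_statistics(outcomes)

    # true-score learning effects (regulation learning uncontaminated by sham display)
    for label, key in (("displayed", "displayed_summaries"), ("true", "true_summaries")):
        for grp in ("NF", "Sham"):
            les = [
                learning_effects_from_summaries(getattr(res, key))
                for res in results
                if res.group == grp
            ]
            if les:
                report.setdefault("learning_effects", {})[f"{grp}_{label}"] = {
                    "le_score_mean": float(np.mean([d["le_score"] for d in les])),
                    "le_ca_mean": float(np.mean([d["le_ca"] for d in les])),
                }

    if sham_subjects and sham_model is not None:
        sham_results = [res for res in results if res.group == "Sham"]
        disp = np.concatenate([res.displayed_scores.ravel() for res in sham_results])
        true = np.concatenate([res.true_scores.ravel() for res in sham_results])
        r = float(np.corrcoef(disp, true)[0, 1]) if disp.size > 1 else float("nan")
        report["sham_validation"] = {
            "n_trials": int(disp.size),
            "displayed_vs_true_r": r,
            "run_success_rates": list(sham_model.run_success_rates_),
        }

    if config.compute_mvpa:
        mvpa: Dict[str, Dict[str, float]] = {}
        for grp in ("NF", "Sham"):
            grp_res = [res for res in results if res.group == grp]
            if grp_res:
                mvpa[grp] = {
                    str(r): float(np.mean([res.offline_ca[r] for res in grp_res]))
                    for r in range(4)
                }
        report["offline_mvpa_mean_ca"] = mvpa

    return report


def simulate_sham_arm_scores(
    n_sham: int = 26,
    seed: int = 0,
    config: Optional[ExperimentConfig] = None,
) -> Dict[str, np.ndarray]:
    """Displayed vs true scores of a sham arm, for independence checks.

    Runs the full loop with MVPA and behaviour disabled and returns the
    pooled per-trial displayed and true scores (n_sham x 3 x 24 each,
    flattened).
    """
    import dataclasses

    if config is None:
        config = ExperimentConfig()
    report_cfg = dataclasses.replace(
        config, n_sham=n_sham, compute_mvpa=False, simulate_behaviour=False
    )
    ss = np.random.SeedSequence(seed)
    cohort_ss, session_ss = ss.spawn(2)
    subjects = simulate_cohort(
        report_cfg.n_nf,
        n_sham,
        report_cfg.population,
        seed=int(cohort_ss.generate_state(1)[0] % (2**31)),
        params=report_cfg.acquisition,
    )
    session_seeds = session_ss.spawn(len(subjects))
    nf_subjects = [s for s in subjects if s.params.group == "NF"]
    sham_subjects = [s for s in subjects if s.params.group == "Sham"]

    nf_results = [
        run_subject_session(subj, None, report_cfg, s)
        for subj, s in zip(nf_subjects, session_seeds[: len(nf_subjects)])
    ]
    scores_by_run = [
        np.concatenate([res.displayed_scores[r] for res in nf_results]) for r in range(3)
    ]
    sham_model = ShamScoreGenerator(
        bin_width=report_cfg.sham_bin_width, estimate_rates=report_cfg.estimate_sham_rates
    ).fit(scores_by_run)

    disp, true = [], []
    for subj, s in zip(sham_subjects, session_seeds[len(nf_subjects) :]):
        res = run_subject_session(subj, sham_model, report_cfg, s)
        disp.append(res.displayed_scores.ravel())
        true.append(res.true_scores.ravel())
    return {"displayed": np.concatenate(disp), "true": np.concatenate(true)}
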