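import numpy as np
import pytest

from decnef.preprocess import psc_from_run
from decnef.mvpa import run_offline_cv
from decnef.schedule import AcquisitionParams, RunKind, build_schedule
from decnef.synth import (
    HEARTBEAT_DURATIONS,
    PopulationConfig,
    SubjectParams,
    simulate_cohort,
    simulate_heartbeat_session,
    simulate_run,
)


def _subject(n_vox=20, **kw):
    rng = np.random.default_rng(kw.pop("pattern_seed", 0))
    base = dict(
        subject_id="s01",
        group="NF",
        learnability=0.0,
        pattern_intero=rng.normal(0, 1.0, n_vox),
        pattern_extero=rng.normal(0, 1.0, n_vox),
        noise_sd=1.0,
        ar1_rho=0.3,
        drift_amplitude=0.5,
        run_amplitude_sd=0.0,
    )
    base.update(kw)
    return SubjectParams(**base)


class TestSimulateRun:
    def test_degenerate_inputs_give_constant_baseline(self, small_params, regulation_schedule):
        sp = _subject(
            pattern_intero=np.zeros(20),
            pattern_extero=np.zeros(20),
            noise_sd=0.0,
            drift_amplitude=0.0,
            baseline_level=500.0,
        )
        run = simulate_run(regulation_schedule, sp, 1, seed=0, params=small_params)
        assert np.allclose(run.data, 500.0)

    def test_deterministic_given_seed(self, small_params, regulation_schedule):
        sp = _subject()
        a = simulate_run(regulation_schedule, sp, 1, seed=9, params=small_params)
        b = simulate_run(regulation_schedule, sp, 1, seed=9, params=small_params)
        assert np.array_equal(a.data, b.data)

    def test_zero_learnability_keeps_amplitude_constant_across_runs(
        self, small_params, regulation_schedule
    ):
        sp = _subject(noise_sd=0.0, drift_amplitude=0.0)
        r1 = simulate_run(regulation_schedule, sp, 1, seed=0, params=small_params)
        r3 = simulate_run(regulation_schedule, sp, 3, seed=0, params=small_params)
        assert np.allclose(r1.data, r3.data)

    def test_learnability_scales_regulation_amplitude_for_contingent_group(
        self, small_params, regulation_schedule
    ):
        sp = _subject(learnability=0.5, noise_sd=0.0, drift_amplitude=0.0, baseline_level=1000.0)
        r1 = simulate_run(regulation_schedule, sp, 1, seed=0, params=small_params)
        r3 = simulate_run(regulation_schedule, sp, 3, seed=0, params=small_params)
        dev1 = np.abs(r1.data - 1000.0).max()
        dev3 = np.abs(r3.data - 1000.0).max()
        assert dev3 == pytest.approx(dev1 * 2.5 / 1.5, rel=1e-9)

    def test_sham_group_never_scales(self, small_params, regulation_schedule):
        sp = _subject(group="Sham", learnability=0.9, noise_sd=0.0, drift_amplitude=0.0)
        r1 = simulate_run(regulation_schedule, sp, 1, seed=0, params=small_params)
        r3 = simulate_run(regulation_schedule, sp, 3, seed=0, params=small_params)
        assert np.allclose(r1.data, r3.data)

    def test_high_snr_subject_decodes_almost_perfectly(self, small_params, task_schedule):
        sp = _subject(pattern_seed=4, noise_sd=0.05, drift_amplitude=0.0)
        run = simulate_run(task_schedule, sp, 0, seed=2, params=small_params)
        psc = psc_from_run(run.data, task_schedule, small_params)
        assert run_offline_cv(psc, task_schedule, small_params) >= 0.95


class TestSimulateCohort:
    def test_default_counts(self):
        subjects = simulate_cohort(3, 2, seed=0, params=AcquisitionParams(n_voxels=5))
        assert sum(s.params.group == "NF" for s in subjects) == 3
        assert sum(s.params.group == "Sham" for s in subjects) == 2
        assert all(len(s.runs) == 4 for s in subjects)

    def test_same_seed_reproduces_cohort(self):
        p = AcquisitionParams(n_voxels=5)
        a = simulate_cohort(2, 1, seed=7, params=p)
        b = simulate_cohort(2, 1, seed=7, params=p)
        for sa, sb in zip(a, b):
            assert sa.params.learnability == sb.params.learnability
            for ra, rb in zip(sa.runs, sb.runs):
                assert np.array_equal(ra.data, rb.data)

    def test_empty_nf_arm_allowed(self):
        subjects = simulate_cohort(0, 2, seed=0, params=AcquisitionParams(n_voxels=5))
        assert len(subjects) == 2
        assert all(s.params.group == "Sham" for s in subjects)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(-1, 2, seed=0)

    def test_learnability_mixture_contains_nonlearners(self):
        pop = PopulationConfig(nonlearner_fraction=0.4)
        subjects = simulate_cohort(40, 0, pop, seed=3, params=AcquisitionParams(n_voxels=2))
        lams = np.array([s.params.learnability for s in subjects])
        assert (lams == 0).any() and (lams > 0).any()


class TestHeartbeatSession:
    def test_one_trial_per_duration(self):
        trials = simulate_heartbeat_session(_subject(n_vox=2), "pre", 0.0, seed=0)
        assert tuple(t.duration_seconds for t in trials) == HEARTBEAT_DURATIONS

    def test_perfect_perception_zero_noise_gives_accuracy_one(self):
        from decnef.behaviour import interoceptive_accuracy

        sp = _subject(n_vox=2, perception_fraction_pre=1.0, behaviour_coupling=0.0)
        trials = simulate_heartbeat_session(
            sp, "pre", 0.0, seed=0, perception_jitter_sd=0.0, report_noise_sd=0.0
        )
        assert interoceptive_accuracy(trials) == pytest.approx(1.0)

    def test_nonzero_learning_effect_rejected_for_pre(self):
        with pytest.raises(ValueError):
            simulate_heartbeat_session(_subject(n_vox=2), "pre", 0.5, seed=0)

    def test_positive_coupling_raises_post_accuracy_in_expectation(self):
        from decnef.behaviour import interoceptive_accuracy

        sp = _subject(n_vox=2, perception_fraction_pre=0.5, behaviour_coupling=1.0)
        pre, post = [], []
        for seed in range(60):
            pre.append(
                interoceptive_accuracy(simulate_heartbeat_session(sp, "pre", 0.0, seed=seed))
            )
            post.append(
                interoceptive_accuracy(simulate_heartbeat_session(sp, "post", 0.3, seed=seed + 500))
            )
        assert np.mean(post) > np.mean(pre)

    def test_sham_group_ignores_learning_effect(self):
        sp = _subject(n_vox=2, group="Sham", perception_fraction_pre=0.5, behaviour_coupling=1.0)
        a = simulate_heartbeat_session(
            sp, "post", 0.4, seed=3, perception_jitter_sd=0.0, report_noise_sd=0.0
        )
        b = simulate_heartbeat_session(
            sp, "post", 0.0, seed=3, perception_jitter_sd=0.0, report_noise_sd=0.0
        )
        assert [t.reported_beats for t in a] == [t.reported_beats for t in b]


class TestNullSeparability:
    def test_zero_patterns_give_chance_level_decoding(self, small_params, regulation_schedule):
        # decoder CA distribution centred on 0.5 when no signal exists
        accs = []
        for seed in range(30):
            sp = _subject(
                pattern_intero=np.zeros(20), pattern_extero=np.zeros(20), drift_amplitude=0.0
            )
            run = simulate_run(regulation_schedule, sp, 1, seed=seed, params=small_params)
            psc = psc_from_run(run.data, regulation_schedule, small_params)
            accs.append(run_offline_cv(psc, regulation_schedule, small_params))
        from scipy import stats

        # binomial-style check: mean not significantly off 0.5
        t, p = stats.ttest_1samp(accs, 0.5)
        assert p > 0.01
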