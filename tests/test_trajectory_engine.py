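import numpy as np
import pytest

from acasim.param_space import DeclineParams, LearningParams
from acasim.study_model import TransitionRules, default_cutoffs
from acasim.subject_model import (
    SubjectProfile,
    decline_multiplier,
    learning_multiplier,
)
from acasim.trajectory_engine import (
    CohortSpec,
    StudySpec,
    Trajectory,
    build_schedule,
    simulate_cohort,
    simulate_subject,
)

from conftest import constant_instrument


def unreachable_rules(n_ranks=5, n_consec=1):
    return TransitionRules(
        promote_cutoffs=(1e9,) * n_ranks,
        demote_cutoffs=(-1e9,) * n_ranks,
        n_consec_up=n_consec,
        n_consec_down=n_consec,
    )


def make_study(spec, paradigm="fixed_rank", run_in=14, total=30, adaptive_rules=None):
    return StudySpec(
        run_in_runs=run_in,
        total_runs=total,
        paradigm=paradigm,
        rules_run_in=adaptive_rules or unreachable_rules(spec.n_ranks),
        rules_evaluation=adaptive_rules or unreachable_rules(spec.n_ranks),
    )


def make_profile(spec, learning=None, decline=None, sid=1):
    return SubjectProfile(
        sid,
        learning or LearningParams(1.0, 0.2),
        decline or DeclineParams(0.0, 14),
        spec,
    )


class TestBuildSchedule:
    def test_default_four_year_study(self):
        # 14 daily runs then weekly testing through a 208-week horizon
        assert build_schedule(4, run_in_days=14, evaluation_interval_days=7) == 220

    def test_run_in_only(self):
        assert build_schedule(14 / 364, 14, 7) == 14

    def test_one_year(self):
        assert build_schedule(1, 14, 7) == 64

    def test_horizon_shorter_than_run_in_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            build_schedule(7 / 364, 14, 7)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            build_schedule(0, 14, 7)


class TestSimulateSubject:
    def test_fixed_rank_constant_after_run_in(self, flat_instrument):
        rules = default_cutoffs(flat_instrument, n_consec_up=1, n_consec_down=1)
        study = StudySpec(
            run_in_runs=14,
            total_runs=60,
            paradigm="fixed_rank",
            rules_run_in=rules,
            rules_evaluation=rules,
        )
        traj = simulate_subject(
            make_profile(flat_instrument), study, np.random.default_rng(3)
        )
        baseline_rank = traj.ranks[13]
        assert np.all(traj.ranks[13:] == baseline_rank)

    def test_trajectory_contract(self, flat_instrument):
        study = make_study(flat_instrument, total=25)
        traj = simulate_subject(
            make_profile(flat_instrument), study, np.random.default_rng(0)
        )
        assert len(traj) == 25
        assert np.array_equal(traj.runs, np.arange(1, 26))
        assert np.all((traj.ranks >= 1) & (traj.ranks <= flat_instrument.n_ranks))
        assert np.all(traj.scores >= flat_instrument.score_floor)
        assert list(traj.phase[:14]) == ["run_in"] * 14
        assert set(traj.phase[14:]) == {"evaluation"}

    def test_degenerate_chain_repeats_first_draw(self):
        spec = constant_instrument(mu=50.0, sigma=10.0, rho=1.0)
        study = make_study(spec, total=20)
        traj = simulate_subject(make_profile(spec), study, np.random.default_rng(1))
        assert np.allclose(traj.scores, traj.scores[0])

    def test_determinism_and_seed_sensitivity(self, flat_instrument):
        study = make_study(flat_instrument, total=30)
        t1 = simulate_subject(
            make_profile(flat_instrument), study, np.random.default_rng(7)
        )
        t2 = simulate_subject(
            make_profile(flat_instrument), study, np.random.default_rng(7)
        )
        t3 = simulate_subject(
            make_profile(flat_instrument), study, np.random.default_rng(8)
        )
        assert np.array_equal(t1.scores, t2.scores)
        assert not np.array_equal(t1.scores, t3.scores)

    def test_adaptive_transitions_replay_reference_interpreter(self):
        # replay the rank sequence with an independent streak-tracking
        # interpreter of the transition rules
        spec = constant_instrument(mu=50.0, sigma=10.0, rho=0.6)
        rules = default_cutoffs(spec, n_consec_up=2, n_consec_down=2)
        study = StudySpec(
            run_in_runs=5,
            total_runs=80,
            paradigm="adaptive_rank",
            rules_run_in=default_cutoffs(spec, n_consec_up=1, n_consec_down=1),
            rules_evaluation=rules,
        )
        traj = simulate_subject(make_profile(spec), study, np.random.default_rng(42))

        rank = traj.ranks[0]
        streak: list[float] = []
        for k in range(1, len(traj) + 1):
            assert traj.ranks[k - 1] == rank
            streak.append(traj.scores[k - 1])
            if k == len(traj):
                break
            r = study.rules_run_in if k + 1 <= study.run_in_runs else rules
            n_up, n_down = r.n_consec_up, r.n_consec_down
            new = rank
            if (
                rank < spec.n_ranks
                and len(streak) >= n_up
                and all(s > r.promote_cutoff(rank) for s in streak[-n_up:])
            ):
                new = rank + 1
            elif (
                rank > 1
                and len(streak) >= n_down
                and all(s < r.demote_cutoff(rank) for s in streak[-n_down:])
            ):
                new = rank - 1
            if new != rank:
                streak = []
                rank = new


class TestSimulateCohort:
    def test_cohort_shape(self, flat_instrument, no_learning, no_decline):
        cohort = CohortSpec(
            n_subjects=10,
            decline=no_decline,
            learning=no_learning,
            instrument=flat_instrument,
        )
        study = make_study(flat_instrument, total=20)
        trajs = simulate_cohort(cohort, study, seed=5)
        assert len(trajs) == 10
        assert all(len(t) == 20 for t in trajs)
        assert [t.subject_id for t in trajs] == list(range(1, 11))

    def test_bit_reproducible(self, flat_instrument, no_learning, no_decline):
        cohort = CohortSpec(5, no_decline, no_learning, flat_instrument)
        study = make_study(flat_instrument, total=20)
        a = simulate_cohort(cohort, study, seed=9)
        b = simulate_cohort(cohort, study, seed=9)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.scores, tb.scores)
            assert np.array_equal(ta.ranks, tb.ranks)

    def test_null_cohort_mean_flat_over_runs(self, flat_instrument):
        # no learning, no decline: the cohort mean score has no trend
        cohort = CohortSpec(
            400, DeclineParams(0.0, 14), LearningParams(1.0, 0.2), flat_instrument
        )
        study = make_study(flat_instrument, total=40)
        trajs = simulate_cohort(cohort, study, seed=11)
        scores = np.vstack([t.scores for t in trajs])
        se = 10.0 / np.sqrt(400)
        assert np.all(np.abs(scores.mean(axis=0) - 50.0) < 4 * se)

    def test_cohort_mean_tracks_multiplier_product(self):
        # with constant parameters at a fixed rank the empirical mean at
        # run j is mu * L(j) * D(j) within Monte-Carlo error
        spec = constant_instrument(mu=50.0, sigma=10.0, rho=0.7)
        learning = LearningParams(1.3, 0.2)
        decline = DeclineParams(0.01, 5)
        cohort = CohortSpec(2000, decline, learning, spec)
        study = make_study(spec, run_in=5, total=30)
        trajs = simulate_cohort(cohort, study, seed=21)
        scores = np.vstack([t.scores for t in trajs])
        runs = np.arange(1, 31)
        expected = (
            50.0
            * learning_multiplier(learning, runs)
            * decline_multiplier(decline, runs)
        )
        se = 10.0 / np.sqrt(2000)
        assert np.all(np.abs(scores.mean(axis=0) - expected) < 3.5 * se)

    def test_declining_cohort_expectation_drops(self):
        d = DeclineParams(0.002, 14)
        assert decline_multiplier(d, 220) < decline_multiplier(d, 20)


class TestTrajectoryExport:
    def test_long_format_frame(self, flat_instrument, no_learning, no_decline):
        from acasim.trajectory_engine import trajectories_to_frame

        cohort = CohortSpec(3, no_decline, no_learning, flat_instrument)
        study = make_study(flat_instrument, total=16)
        df = trajectories_to_frame(simulate_cohort(cohort, study, seed=2))
        assert list(df.columns) == ["subject_id", "run", "phase", "rank", "score"]
        assert len(df) == 3 * 16
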