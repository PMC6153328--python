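import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vmadapt.cohort import (
    CohortConfig,
    CohortConfigError,
    LearnerParams,
    default_cohort_config,
    render_trajectory,
    sample_cohort_params,
    samples_to_string,
    simulate_cohort,
    simulate_subject,
    string_to_samples,
)
from vmadapt.kinematics import analyze_trial_log, hand_angle, rt_mt
from vmadapt.metrics import subject_summary


def two_process_oracle(schedule, eta, A, B, cap=60.0):
    """Independent iteration of the learner recurrences (no noise, grid snap)."""
    xe = xi = 0.0
    hands, xes, xis = [], [], []
    for row in schedule.itertuples(index=False):
        xes.append(xe)
        xis.append(xi)
        if row.report:
            number = int(np.clip(np.rint(-np.clip(xe, -cap, cap) / 5.625), -31, 31))
            aim = -number * 5.625
        else:
            aim = 0.0
        hand = aim + xi
        cursor = hand + row.rotation_deg
        if row.feedback != "none":
            if row.report:
                xe = xe - eta * cursor
            xi = A * xi - B * (cursor - aim)
        else:
            xi = A * xi
        hands.append(hand)
    return np.array(hands), np.array(xes), np.array(xis)


class TestSampleCohortParams:
    def test_deterministic(self):
        cfg = default_cohort_config("exp1", n_per_group=5, seed=0)
        a = sample_cohort_params(cfg, np.random.default_rng(3))
        b = sample_cohort_params(cfg, np.random.default_rng(3))
        assert [(s, p) for s, p, _ in a] == [(s, p) for s, p, _ in b]

    def test_zero_outlier_fraction_degenerates(self):
        cfg = default_cohort_config("exp1", n_per_group=50, seed=0, outlier_fraction=0.0)
        drawn = sample_cohort_params(cfg, np.random.default_rng(1))
        assert not any(flag for _, _, flag in drawn)

    def test_mixture_weight_matches_outlier_fraction(self):
        # brute-force count of mixture labels over a large draw
        cfg = default_cohort_config("exp1", n_per_group=4000, arms=("SHAM",),
                                    seed=0, outlier_fraction=0.1)
        drawn = sample_cohort_params(cfg, np.random.default_rng(7))
        frac = np.mean([flag for _, _, flag in drawn])
        se = np.sqrt(0.1 * 0.9 / 4000)
        assert abs(frac - 0.1) < 3 * se

    def test_invalid_config_rejected(self):
        with pytest.raises(CohortConfigError):
            default_cohort_config("exp1", n_per_group=1)
        cfg = default_cohort_config("exp1", n_per_group=5)
        bad = dataclasses.replace(cfg.arms["SHAM"]["eta_explicit"], sd=-0.1)
        with pytest.raises(CohortConfigError):
            CohortConfig(
                arms={"SHAM": {**cfg.arms["SHAM"], "eta_explicit": bad}},
                group_sizes={"SHAM": 5},
            )


class TestSimulateSubject:
    def test_non_learner_stays_at_zero(self, exp1_schedule):
        params = LearnerParams(eta_explicit=0.0, A_implicit=0.98, B_implicit=0.0,
                               sigma_motor=0.0, sigma_report=0.0)
        log = simulate_subject(params, exp1_schedule, np.random.default_rng(0), render=False)
        assert np.allclose(log.trials["hand_deg"], 0.0)
        rot = log.trials[log.trials["block"] == "rotation"]
        assert np.allclose(rot["hand_deg"] + rot["rotation_deg"], -45.0)

    def test_purely_explicit_learner_has_zero_implicit(self, exp1_schedule):
        params = LearnerParams(eta_explicit=0.3, A_implicit=0.98, B_implicit=0.0,
                               sigma_motor=0.0, sigma_report=1.0)
        log = simulate_subject(params, exp1_schedule, np.random.default_rng(1), render=False)
        kin = analyze_trial_log(log.trials)
        summary = subject_summary(log.trials, kin)
        # hand is built from the snapped reported aim, so hand - aim == 0
        assert summary["implicit_deg"] == pytest.approx(summary["baseline_bias_deg"] * -1
                                                        + 0.0, abs=1e-12)
        rot = log.trials[log.trials["block"] == "rotation"]
        merged = rot.merge(kin, on="trial_global")
        aim = -merged["report_number"].to_numpy() * 5.625
        assert np.allclose(merged["hand_angle_deg"], aim)

    def test_matches_independent_recurrence_oracle(self, exp1_schedule, noise_free_params):
        log = simulate_subject(noise_free_params, exp1_schedule,
                               np.random.default_rng(0), render=False)
        hands, xes, xis = two_process_oracle(exp1_schedule, eta=0.2, A=0.98, B=0.05)
        assert np.allclose(log.trials["hand_deg"], hands)
        assert np.allclose(log.states["explicit_state_deg"], xes)
        assert np.allclose(log.states["implicit_state_deg"], xis)

    def test_noise_free_learner_converges_near_full_compensation(
        self, exp1_schedule, noise_free_params
    ):
        log = simulate_subject(noise_free_params, exp1_schedule,
                               np.random.default_rng(0), render=False)
        rot = log.trials[log.trials["block"] == "rotation"]
        late = rot["hand_deg"].to_numpy()[-40:]
        # aim snaps to the 5.625 deg number grid, so single trials can sit one
        # grid step off; the late-block average converges on full compensation
        assert abs(late.mean() - 45.0) < 3.0
        assert np.all(np.abs(late - 45.0) < 5.625)
        # implicit settles at the fixed point of the iterated recurrences
        _, _, xis = two_process_oracle(exp1_schedule, eta=0.2, A=0.98, B=0.05)
        assert log.states["implicit_state_deg"].iloc[-181] == pytest.approx(xis[-181])

    def test_hidden_state_conservation(self, exp1_schedule):
        # hand - aim - implicit_state is pure motor noise with mean ~ 0
        params = LearnerParams(eta_explicit=0.15, A_implicit=0.98, B_implicit=0.02,
                               sigma_motor=3.0, sigma_report=1.0)
        rng = np.random.default_rng(5)
        resid = []
        for _ in range(30):  # ~10k trials total
            log = simulate_subject(params, exp1_schedule, rng, render=False)
            resid.append(
                log.states["hand_deg_true"].to_numpy()
                - log.states["aim_deg"].to_numpy()
                - log.states["implicit_state_deg"].to_numpy()
            )
        resid = np.concatenate(resid)
        assert abs(resid.mean()) < 3 * resid.std(ddof=1) / np.sqrt(resid.size)


class TestRenderTrajectory:
    def test_straight_reach_recovered_exactly(self):
        traj = render_trajectory(0.0, rt=0.5, mt=0.3)
        assert hand_angle(traj, 0.0) == pytest.approx(0.0, abs=1e-6)
        traj = render_trajectory(30.0, rt=0.5, mt=0.3)
        assert hand_angle(traj, 0.0) == pytest.approx(30.0, abs=1e-6)

    def test_sampling_grid_and_extent(self):
        traj = render_trajectory(10.0, rt=0.4, mt=0.35)
        assert np.allclose(np.diff(traj[:, 0]), 0.01)
        r = np.hypot(traj[:, 1], traj[:, 2])
        assert r[0] < 0.25
        assert r.max() >= 7.2

    def test_rt_mt_round_trip(self):
        traj = render_trajectory(0.0, rt=0.5, mt=0.3)
        rt, mt, slow = rt_mt(traj)
        assert rt == pytest.approx(0.5, abs=0.01)
        assert mt == pytest.approx(0.3, abs=0.01)
        assert not slow

    def test_slow_movement_flagged(self):
        traj = render_trajectory(0.0, rt=0.3, mt=0.5)
        _, mt, slow = rt_mt(traj)
        assert mt == pytest.approx(0.5, abs=0.01)
        assert slow

    def test_curvature_stays_within_bound(self):
        rng = np.random.default_rng(0)
        for hand in (0.0, 120.0, -90.0):
            for _ in range(20):
                traj = render_trajectory(hand, 0.4, 0.3, rng, curvature_noise_deg=0.2)
                err = hand_angle(traj, 0.0) - hand
                assert abs((err + 180) % 360 - 180) < 0.55  # 2.5 sd clip + interp slack

    def test_invalid_movement_time_rejected(self):
        with pytest.raises(ValueError):
            render_trajectory(0.0, rt=0.3, mt=0.0)


class TestSimulateCohort:
    def test_file_and_manifest_counts(self, tmp_path):
        cfg = default_cohort_config("exp1", n_per_group=2, seed=1,
                                    render_trajectories=False)
        res = simulate_cohort(cfg, out_dir=tmp_path)
        assert len(res.logs) == 6
        assert len(res.manifest) == 6
        assert len(list(tmp_path.glob("*.states.tsv"))) == 6
        assert (tmp_path / "manifest.tsv").exists()

    def test_byte_identical_reruns(self, tmp_path):
        cfg = default_cohort_config("exp1", n_per_group=2, seed=9,
                                    render_trajectories=True)
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_cohort(cfg, out_dir=a)
        simulate_cohort(cfg, out_dir=b)
        for pa in sorted(a.iterdir()):
            assert pa.read_bytes() == (b / pa.name).read_bytes()

    def test_decomposition_identity_without_motor_noise(self, exp1_schedule):
        # pipeline-computed implicit equals the hidden implicit state exactly
        params = LearnerParams(eta_explicit=0.15, A_implicit=0.98, B_implicit=0.03,
                               sigma_motor=0.0, sigma_report=1.0)
        log = simulate_subject(params, exp1_schedule, np.random.default_rng(2), render=False)
        kin = analyze_trial_log(log.trials)
        merged = log.trials.merge(
            kin[["trial_global", "hand_angle_deg", "valid"]], on="trial_global"
        ).merge(log.states[["trial_global", "implicit_state_deg"]], on="trial_global")
        rot = merged[(merged["block"] == "rotation") & merged["report_number"].notna()]
        implicit_pipeline = rot["hand_angle_deg"] + rot["report_number"] * 5.625
        assert np.allclose(implicit_pipeline, rot["implicit_state_deg"], atol=1e-9)

    def test_parameter_recovery_rank_correlation(self):
        # higher implicit error sensitivity -> higher pipeline implicit mean
        cfg = default_cohort_config("exp1", n_per_group=100, arms=("SHAM",),
                                    seed=21, render_trajectories=False)
        res = simulate_cohort(cfg)
        implicit_means = []
        for log in res.logs:
            kin = analyze_trial_log(log.trials)
            implicit_means.append(subject_summary(log.trials, kin)["implicit_deg"])
        true_b = res.manifest["true_B_implicit"].to_numpy()
        rho = sps.spearmanr(true_b, implicit_means).statistic
        assert rho > 0.5

    def test_configured_arm_contrast_has_expected_sign(self):
        # CB-like (high B) vs SHAM-like cohorts: implicit-mean difference
        # carries the configured sign in nearly all replicates
        wins = 0
        n_rep = 40
        for rep in range(n_rep):
            cfg = default_cohort_config("exp2", n_per_group=25, arms=("CB", "SHAM"),
                                        seed=1000 + rep, render_trajectories=False)
            res = simulate_cohort(cfg)
            vals = {"CB": [], "SHAM": []}
            for log in res.logs:
                kin = analyze_trial_log(log.trials)
                vals[log.arm].append(subject_summary(log.trials, kin)["implicit_deg"])
            wins += np.mean(vals["CB"]) > np.mean(vals["SHAM"])
        assert wins / n_rep >= 0.95


class TestSampleSerialization:
    def test_round_trip(self):
        traj = render_trajectory(25.0, 0.3, 0.3)
        back = string_to_samples(samples_to_string(traj))
        assert np.allclose(back, traj, atol=1e-5)
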