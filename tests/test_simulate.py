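"""Synthetic-cohort generation: draws, rendering, and inversion."""

import warnings

import numpy as np
import pytest

from vantage.circular import FixationData, GroupParams
from vantage.preprocess import (apply_exclusions, detect_fixations,
                                mean_record_rate, view_angle, wrap_angle)
from vantage.sessions import read_trajectory_tsv, write_trajectory_tsv
from vantage.simulate import (
    OrbitConfig, RateConfig, SimulationConfig, render_trajectory,
    sample_vonmises, simulate_cohort, simulate_fixation_cohort,
)


def _bessel_ratio_series(k, terms=120):
    # A(k) = I1(k)/I0(k) from the power series of both Bessel functions
    i0, i1 = 1.0, 0.0
    term = 1.0
    for m in range(terms):
        if m > 0:
            term *= (0.25 * k * k) / (m * m)
        i0 += term if m > 0 else 0.0
        i1 += term * (0.5 * k) / (m + 1.0)
    return i1 / (1.0 + (i0 - 1.0))


class TestSampleVonMises:
    def test_uniform_limit_resultant(self):
        th = sample_vonmises(0.0, 0.0, 10_000, seed=0)
        R = np.hypot(np.cos(th).sum(), np.sin(th).sum()) / len(th)
        assert R < 0.03

    def test_concentrated_matches_bessel_ratio_oracle(self):
        mu, k = 0.8, 5.0
        th = sample_vonmises(mu, k, 10_000, seed=1)
        mean_dir = np.arctan2(np.sin(th).sum(), np.cos(th).sum())
        R = np.hypot(np.cos(th).sum(), np.sin(th).sum()) / len(th)
        assert wrap_angle(mean_dir - mu) == pytest.approx(0.0, abs=0.05)
        assert R == pytest.approx(_bessel_ratio_series(k), abs=0.02)

    def test_seed_reproducibility_and_interval(self):
        a = sample_vonmises(0.4, 2.0, 500, seed=7)
        b = sample_vonmises(0.4, 2.0, 500, seed=7)
        assert np.array_equal(a, b)
        assert np.all((a > -np.pi) & (a <= np.pi))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sample_vonmises(0.0, -1.0, 10)
        with pytest.raises(ValueError):
            sample_vonmises(0.0, 1.0, 0)


class TestRenderTrajectory:
    def test_single_fixation_constant_log(self):
        t, cam, tgt, phase = render_trajectory([(0.3, 5.0, 2000)])
        assert len(np.unique(cam, axis=0)) == 1
        assert t[-1] - t[0] >= 2000 - 17

    def test_roundtrip_recovers_planned_fixations(self):
        plan = [(0.2, 5.0, 600), (-0.7, 4.0, 900)]
        t, cam, tgt, phase = render_trajectory(plan, rng=0)
        from vantage.sessions import Session
        s = Session("p", 0, t, cam, tgt, phase)
        fx = detect_fixations(s, min_dwell_ms=500)
        assert fx.n_events == 2
        np.testing.assert_allclose(fx.theta, [0.2, -0.7], atol=1e-9)
        # dwell recovered within one frame interval (60 Hz)
        np.testing.assert_allclose(fx.dwell, [600, 900], atol=17.5)

    def test_transit_arc_length_matches_r_dtheta(self):
        r, th0, th1 = 5.0, 0.0, 1.2
        plan = [(th0, r, 600), (th1, r, 600)]
        t, cam, tgt, phase = render_trajectory(
            plan, OrbitConfig(angular_speed=0.8), RateConfig(nominal_hz=60))
        # chord-length sum over the transit approximates the arc length
        steps = np.linalg.norm(np.diff(cam, axis=0), axis=1)
        total = steps.sum()
        assert total == pytest.approx(r * (th1 - th0), rel=0.01)

    def test_rate_regime_controls_frame_count(self):
        plan = [(0.0, 5.0, 10_000)]
        t60, *_ = render_trajectory(plan, rate=RateConfig(nominal_hz=60))
        t10, *_ = render_trajectory(plan, rate=RateConfig(nominal_hz=10))
        assert len(t60) == pytest.approx(6 * len(t10), rel=0.05)

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            render_trajectory([])


class TestSimulateCohort:
    def test_minimal_cohort(self):
        cfg = SimulationConfig(n_per_condition=(1, 1, 1),
                               fixation_count_mean=1.0,
                               fixation_count_dispersion=1e6, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort, truth = simulate_cohort(cfg)
        assert len(cohort) == 3
        seqs = [detect_fixations(s) for s in cohort.sessions]
        # every planned fixation (and nothing else) survives detection
        assert [s.n_events for s in seqs] == list(truth["n_fix"])

    def test_generated_logs_roundtrip_through_tsv(self, tmp_path):
        cfg = SimulationConfig(n_per_condition=(2, 1, 1), seed=3)
        cohort, _ = simulate_cohort(cfg)
        for s in cohort.sessions[:2]:
            path = tmp_path / f"{s.participant_id}.tsv"
            write_trajectory_tsv(s, path)
            back = read_trajectory_tsv(path, s.participant_id, s.condition)
            assert back == s
            assert back.n_rejected_rows == 0

    def test_main_phase_spans_trial_and_rate_cap(self):
        cfg = SimulationConfig(n_per_condition=(2, 2, 2), seed=4)
        cohort, _ = simulate_cohort(cfg)
        for s in cohort.sessions:
            t, _, _ = s.phase_arrays("main")
            assert t[-1] - t[0] >= 99_000
            assert mean_record_rate(s, "main") <= 60.5

    def test_detected_angles_match_generating_von_mises(self):
        # per-participant fixation angles come from VM(mu_i, kappa_i)
        cfg = SimulationConfig(n_per_condition=(4, 1, 1), seed=5)
        cohort, truth = simulate_cohort(cfg)
        seqs = [detect_fixations(s) for s in cohort.sessions]
        data = FixationData.from_sequences(seqs)
        for i, seq in enumerate(seqs):
            mu_hat = np.arctan2(np.sin(seq.theta).sum(),
                                np.cos(seq.theta).sum())
            spread = 1.0 / np.sqrt(max(truth["kappa_i"][i], 0.2) *
                                   seq.n_events)
            assert abs(wrap_angle(mu_hat - truth["mu_i"][i])) < 4 * spread + 0.05

    def test_dropout_trips_rate_exclusion(self):
        cfg = SimulationConfig(n_per_condition=(2, 2, 2), seed=6,
                               rate=RateConfig(nominal_hz=60, dropout_p=0.9))
        cohort, _ = simulate_cohort(cfg)
        # 60 Hz with 90% dropout -> ~6 rec/s: everyone below the floor
        _, report = apply_exclusions(cohort)
        assert report.counts["low_rate"] == 6

    def test_practice_phase_present_for_covariate(self):
        cfg = SimulationConfig(n_per_condition=(2, 1, 1), seed=7)
        cohort, _ = simulate_cohort(cfg)
        from vantage.metrics import movement_summary
        for s in cohort.sessions:
            m = movement_summary(s)
            assert np.isfinite(m.d_cov)

    def test_likert_shifts_follow_configuration(self):
        cfg = SimulationConfig(n_per_condition=(150, 150, 150), seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seqs, truth = simulate_fixation_cohort(cfg)
        cohort, _ = simulate_cohort(
            SimulationConfig(n_per_condition=(60, 60, 60), seed=8))
        lik = cohort.likert
        cond = {s.participant_id: int(s.condition) for s in cohort.sessions}
        emp = lik.groupby([cond[i] for i in lik.index]).mean()
        # process and creator conditions elevate empathy
        assert emp.loc[1, "empathy"] > emp.loc[0, "empathy"]
        assert emp.loc[2, "empathy"] > emp.loc[0, "empathy"]


class TestConditionLevelConvergence:
    def test_circular_stats_converge_to_group_truth(self):
        # empirical per-condition stats approach the alphas as n grows
        devs = []
        for n in (12, 120):
            cfg = SimulationConfig(n_per_condition=(n, n, n),
                                   seed=9, fixation_count_mean=40.0)
            seqs, truth = simulate_fixation_cohort(cfg)
            mu_bar = []
            for c in (0, 1, 2):
                th = np.concatenate([s.theta for s in seqs
                                     if s.condition == c])
                mu_bar.append(np.arctan2(np.sin(th).sum(), np.cos(th).sum()))
            g = GroupParams(**truth["group"])
            dev = np.abs(wrap_angle(np.array(mu_bar)
                                    - g.alpha_mu_of([0, 1, 2])))
            devs.append(dev.mean())
        assert devs[1] < devs[0]
        assert devs[1] < 0.1
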