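"""Von Mises density, hierarchical log joint, sampler, and diagnostics."""

import warnings

import numpy as np
import pytest
from scipy import integrate

from vantage.circular import (
    FixationData, GroupMarginalPosterior, GroupParams, MCMCConfig,
    ParticipantParams, PriorSpec, UnconstrainedPosterior, fit_model,
    log_joint, posterior_summary, split_rhat, vonmises_logpdf, _delta_logpdf,
)
from vantage.preprocess import FixationSequence


def _seq(thetas, pid="p0", condition=0):
    thetas = np.asarray(thetas, dtype=float)
    return FixationSequence(pid, condition, thetas,
                            np.full(len(thetas), 800.0),
                            np.zeros((len(thetas), 3)))


def _bessel_i0_series(k, terms=80):
    total, term, q = 1.0, 1.0, 0.25 * k * k
    for m in range(1, terms):
        term *= q / (m * m)
        total += term
    return total


class TestVonMisesLogpdf:
    def test_uniform_limit(self):
        for theta in (-3.0, 0.0, 1.2, np.pi):
            assert vonmises_logpdf(theta, 0.0, 0.0) == pytest.approx(
                np.log(1 / (2 * np.pi)), abs=1e-14)

    def test_mode_value_against_series_oracle(self):
        k = 2.0
        expected = k - np.log(2 * np.pi * _bessel_i0_series(k))
        assert vonmises_logpdf(0.3, 0.3, k) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_symmetry_about_mean(self, rng):
        mu, k = 0.7, 3.5
        for x in rng.uniform(0, np.pi, 50):
            assert vonmises_logpdf(mu + x, mu, k) == pytest.approx(
                vonmises_logpdf(mu - x, mu, k), abs=1e-13)

    @pytest.mark.parametrize("kappa", [0.0, 0.5, 2.0, 10.0, 100.0])
    def test_density_normalizes(self, kappa):
        val, err = integrate.quad(
            lambda t: np.exp(vonmises_logpdf(t, 0.4, kappa)),
            -np.pi, np.pi, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            vonmises_logpdf(0.0, 0.0, -1.0)

    def test_stable_at_large_kappa(self):
        v = vonmises_logpdf(0.0, 0.0, 1000.0)
        assert np.isfinite(v) and v == pytest.approx(
            0.5 * np.log(1000.0 / (2 * np.pi)), rel=1e-3)


class TestLogJoint:
    def test_single_fixation_hand_summed(self):
        from scipy import special, stats
        theta = 0.4
        group = GroupParams(alpha_mu=0.2, alpha_kappa=1.5,
                            sigma_mu=0.4, sigma_kappa=0.7)
        part = [ParticipantParams(mu=0.1, kappa=2.0)]
        data = FixationData.from_sequences([_seq([theta])])
        got = log_joint(group, part, data, model="h0", include_prior=False)
        expected = (
            vonmises_logpdf(theta, 0.1, 2.0)
            + stats.norm.logpdf(0.1, 0.2, 0.4)
            + stats.norm.logpdf(2.0, 1.5, 0.7)
            - special.log_ndtr(1.5 / 0.7)
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_nesting_identity_without_priors(self, rng):
        seqs = [_seq(rng.vonmises(0.2, 2.0, 8), f"p{i}", i % 3)
                for i in range(6)]
        data = FixationData.from_sequences(seqs)
        group = GroupParams(alpha_mu=0.3, alpha_kappa=1.7, sigma_mu=0.4,
                            sigma_kappa=0.8)
        parts = (rng.normal(0.3, 0.4, 6), rng.uniform(0.5, 3.0, 6))
        h1 = log_joint(group, parts, data, model="h1", include_prior=False)
        h0 = log_joint(group, parts, data, model="h0", include_prior=False)
        assert h1 == h0   # exact nesting on likelihood + hierarchy

    def test_full_density_differs_by_delta_prior_at_zero(self, rng):
        seqs = [_seq(rng.vonmises(0.2, 2.0, 8), f"p{i}", i % 3)
                for i in range(6)]
        data = FixationData.from_sequences(seqs)
        group = GroupParams(alpha_mu=0.3, alpha_kappa=1.7, sigma_mu=0.4,
                            sigma_kappa=0.8)
        parts = (rng.normal(0.3, 0.4, 6), rng.uniform(0.5, 3.0, 6))
        priors = PriorSpec()
        h1 = log_joint(group, parts, data, priors, model="h1")
        h0 = log_joint(group, parts, data, priors, model="h0")
        assert h1 - h0 == pytest.approx(4 * float(_delta_logpdf(0.0, priors)),
                                        abs=1e-12)

    def test_negative_kappa_is_rejected_state(self):
        data = FixationData.from_sequences([_seq([0.1])])
        group = GroupParams()
        assert log_joint(group, (np.array([0.0]), np.array([-0.5])),
                         data) == -np.inf

    def test_empty_data_prior_only(self):
        data = FixationData(n=np.empty(0), C=np.empty(0), S=np.empty(0),
                            condition=np.empty(0, dtype=int))
        group = GroupParams(alpha_mu=0.1, alpha_kappa=1.0, sigma_mu=0.3,
                            sigma_kappa=0.5)
        from vantage.circular import _log_group_prior_constrained
        got = log_joint(group, (np.empty(0), np.empty(0)), data, model="h0")
        assert got == pytest.approx(
            _log_group_prior_constrained(group, PriorSpec(), "h0"))


class TestSplitRhat:
    def test_iid_chains_near_one(self, rng):
        x = rng.normal(size=(4, 1000))
        assert split_rhat(x) < 1.01

    def test_separated_chains_inflate(self, rng):
        x = rng.normal(size=(2, 500))
        x[1] += 5.0
        assert split_rhat(x) > 1.1

    def test_duplicated_chains_near_one(self, rng):
        c = rng.normal(size=500)
        assert split_rhat(np.vstack([c, c])) == pytest.approx(1.0, abs=0.02)

    def test_constant_chains_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(split_rhat(np.ones((2, 100))))

    def test_matches_arviz_rank_rhat(self, rng):
        import arviz as az
        for _ in range(3):
            x = rng.normal(size=(4, 400)) + rng.normal(
                size=(4, 1))[:, [0]] * 0.3
            mine = split_rhat(x)
            theirs = float(az.rhat(x, method="rank"))
            assert mine == pytest.approx(theirs, abs=1e-10)


class TestPosteriorSummary:
    def test_small_sample_moments(self):
        table = posterior_summary({"x": np.array([1.0, 2.0, 3.0, 4.0])})
        assert table.loc["x", "mean"] == pytest.approx(2.5)
        assert table.loc["x", "sd"] == pytest.approx(np.std([1, 2, 3, 4],
                                                            ddof=1))

    def test_normal_quantiles(self, rng):
        x = rng.standard_normal(100_000)
        table = posterior_summary({"z": x})
        assert table.loc["z", "2.5%"] == pytest.approx(-1.96, abs=0.02)
        assert table.loc["z", "97.5%"] == pytest.approx(1.96, abs=0.02)

    def test_constant_draws(self):
        table = posterior_summary({"c": np.full(50, 3.3)})
        row = table.loc["c"]
        assert row["2.5%"] == pytest.approx(3.3, abs=1e-12)
        assert row["mean"] == pytest.approx(3.3, abs=1e-12)
        assert row["97.5%"] == pytest.approx(3.3, abs=1e-12)
        assert row["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_table_row_order(self, rng):
        seqs = [_seq(rng.vonmises(0.2, 2.0, 10), f"p{i}", i % 3)
                for i in range(9)]
        fit = fit_model(seqs, "h1", mcmc=MCMCConfig(seed=0, warmup=50,
                                                    iters=50))
        assert list(posterior_summary(fit).index) == [
            "sigma_kappa", "alpha_kappa", "delta_kappa_np", "delta_kappa_nc",
            "sigma_mu", "alpha_mu", "delta_mu_np", "delta_mu_nc"]


@pytest.fixture(scope="module")
def small_fit():
    rng = np.random.default_rng(7)
    seqs = [_seq(rng.vonmises(0.3, 2.0, 15), f"p{i}", i % 3)
            for i in range(12)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(seqs, "h1",
                         mcmc=MCMCConfig(seed=5, warmup=400, iters=400))


class TestFitModel:
    def test_seeded_runs_identical(self, rng):
        seqs = [_seq(rng.vonmises(0.3, 2.0, 10), f"p{i}", i % 3)
                for i in range(6)]
        cfg = MCMCConfig(seed=42, warmup=100, iters=100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit_model(seqs, "h1", mcmc=cfg)
            f2 = fit_model(seqs, "h1", mcmc=cfg)
        assert np.array_equal(f1.z, f2.z)

    def test_h0_draws_contain_no_deltas(self, rng):
        seqs = [_seq(rng.vonmises(0.3, 2.0, 10), f"p{i}", i % 3)
                for i in range(6)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(seqs, "h0", mcmc=MCMCConfig(seed=1, warmup=100,
                                                        iters=100))
        assert set(fit.group_names) == {"alpha_mu", "alpha_kappa",
                                        "sigma_mu", "sigma_kappa"}

    def test_concentration_monotonicity(self):
        # one participant's angles made tighter -> larger posterior kappa_i
        rng = np.random.default_rng(3)
        base = rng.vonmises(0.0, 2.0, 40)
        seqs_loose = [_seq(base, "p0", 0), _seq(rng.vonmises(0, 2, 30), "p1", 0)]
        seqs_tight = [_seq(0.25 * base, "p0", 0), seqs_loose[1]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_loose = fit_model(seqs_loose, "h0",
                                mcmc=MCMCConfig(seed=2, warmup=400, iters=400))
            f_tight = fit_model(seqs_tight, "h0",
                                mcmc=MCMCConfig(seed=2, warmup=400, iters=400))
        k_loose = f_loose.participant_draws()[1][:, :, 0].mean()
        k_tight = f_tight.participant_draws()[1][:, :, 0].mean()
        assert k_tight > k_loose

    def test_convergence_report_attached(self, small_fit):
        rep = small_fit.convergence
        assert set(rep.rhat) >= set(small_fit.group_names)
        assert np.isfinite(rep.max_rhat)

    def test_draw_shapes(self, small_fit):
        assert small_fit.z.shape == (4, 400, 8 + 2 * 12)
        mu, kappa = small_fit.participant_draws()
        assert mu.shape == (4, 400, 12)
        assert np.all(kappa > 0)

    def test_long_frame_export(self, small_fit):
        df = small_fit.to_frame()
        assert set(df["parameter"]) == set(small_fit.group_names)
        assert len(df) == 8 * 4 * 400


class TestGroupMarginal:
    """The integrated (participant-free) group posterior used for bridging."""

    def _data(self, rng):
        seqs = [_seq(rng.vonmises(0.3, 2.0, int(n)), f"p{i}", i % 3)
                for i, n in enumerate(rng.integers(2, 40, 12))]
        return FixationData.from_sequences(seqs)

    def test_compiled_matches_numpy_reference(self, rng):
        post = UnconstrainedPosterior(self._data(rng), "h1")
        gm = GroupMarginalPosterior(post)
        zg = np.array([0.3, -0.1, 0.1, np.log(1.7), -0.4, 0.05,
                       np.log(0.4), np.log(0.8)])
        Z = zg[None] + 0.05 * rng.standard_normal((40, 8))
        np.testing.assert_allclose(gm.log_post(Z, compiled=True),
                                   gm.log_post(Z, compiled=False),
                                   rtol=0, atol=1e-8)

    @pytest.mark.parametrize("n_i, mu_t, k_t", [(4, -0.4, 0.6),
                                                (30, 0.2, 2.5)])
    def test_quadrature_against_dblquad_oracle(self, n_i, mu_t, k_t):
        from scipy import special, stats
        rng = np.random.default_rng(11)
        th = rng.vonmises(mu_t, k_t, n_i)
        data = FixationData.from_sequences([_seq(th)])
        post = UnconstrainedPosterior(data, "h0")
        gm = GroupMarginalPosterior(post)
        am, ak, sm, sk = 0.3, 1.6, 0.4, 0.8
        zg = np.array([am, np.log(ak), np.log(sm), np.log(sk)])
        quad = gm.log_post(zg)[0] - post.group_logprior(zg[None])[0]

        C, S, n = np.cos(th).sum(), np.sin(th).sum(), float(n_i)
        shift = quad   # rescale so the oracle integrand is O(1)
        def f(k, mu):
            ll = (k * (C * np.cos(mu) + S * np.sin(mu))
                  - n * (np.log(2 * np.pi) + np.log(special.i0e(k)) + k))
            lp = stats.norm.logpdf(mu, am, sm)
            lk = stats.norm.logpdf(k, ak, sk) - special.log_ndtr(ak / sk)
            return np.exp(ll + lp + lk - shift)
        val, _ = integrate.dblquad(f, -9, 9, 0, 60,
                                   epsabs=1e-12, epsrel=1e-10)
        assert quad == pytest.approx(np.log(val) + shift, abs=5e-3)


class TestSimulationBasedCalibration:
    def test_rank_statistics_uniform(self):
        """SBC at reduced scale: the rank of the generating group mean
        within its posterior draws is uniform when the sampler targets the
        correct posterior."""
        from scipy import stats as sstats
        from vantage.circular import _sbc_ranks

        ranks = _sbc_ranks(n_reps=100, seed=2027)
        counts, _ = np.histogram(ranks, bins=10, range=(0, 20))
        chi2 = ((counts - 10.0) ** 2 / 10.0).sum()
        assert sstats.chi2.sf(chi2, df=9) > 0.01
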