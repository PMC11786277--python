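"""Canned validation studies used by the acceptance harness.

Each function runs one self-contained study at its stated conditions and
returns plain numbers, so the same code backs both the acceptance tests
and the ``scripts/acceptance.py`` reporter.  Sizes are chosen to finish
on a single core in minutes; where a study runs below the full cohort
scale the reduction is noted in its docstring.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from vantage.circular import (FixationData, GroupParams, MCMCConfig,
                              PriorSpec, fit_model, posterior_summary)
from vantage.comparison import BridgeConfig, bridge_log_marginal, model_log_marginal
from vantage.preprocess import apply_exclusions
from vantage.simulate import (STUDY_GROUP_MEANS, SimulationConfig,
                              make_exclusion_cohort, simulate_fixation_cohort)

__all__ = [
    "exclusion_worked_example", "degrees_of_freedom_checks",
    "bridge_toy_study", "recovery_study", "null_recovery_study",
    "evidence_direction_study",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] >> 1)
            for s in np.random.SeedSequence(seed).spawn(n)]


def exclusion_worked_example(seed: int = 0) -> dict:
    """317 participants, criteria flagging 3/17/37 with one double-flag."""
    cohort = make_exclusion_cohort(n_total=317, n_flagged=(3, 17, 37),
                                   n_overlap=1, seed=seed)
    retained, report = apply_exclusions(cohort)
    return {"counts": report.counts, "excluded": report.n_excluded,
            "retained": report.n_retained, "n_input": len(cohort)}


def degrees_of_freedom_checks(seed: int = 0) -> dict:
    """Design-driven degrees of freedom for the classical tests."""
    from vantage.metrics import ancova_oneway, manova_pillai

    rng = np.random.default_rng(seed)
    out = {}
    Y = rng.normal(size=(317, 9))
    g3 = np.repeat([0, 1, 2], [108, 110, 99])
    res = manova_pillai(Y, g3)
    out["manova_df"] = (res.df1, res.df2)
    res = manova_pillai(rng.normal(size=(218, 9)),
                        np.repeat([0, 1], [108, 110]))
    out["pairwise_manova_df"] = (res.df1, res.df2)
    g261 = np.repeat([0, 1, 2], [84, 97, 80])
    anc = ancova_oneway(rng.normal(size=261), g261, rng.normal(size=261))
    out["ancova_df"] = (anc.group.df1, anc.group.df2)
    return out


def bridge_toy_study(seed: int = 0, n_draws: int = 2000) -> dict:
    """Conjugate normal-normal toy: bridge estimate vs closed form."""
    rng = np.random.default_rng(seed)
    n, sigma, mu0, tau0 = 20, 1.3, 0.5, 2.0
    y = rng.normal(1.2, sigma, n)
    prec = n / sigma ** 2 + 1 / tau0 ** 2
    v_post = 1 / prec
    m_post = v_post * (y.sum() / sigma ** 2 + mu0 / tau0 ** 2)
    cov = sigma ** 2 * np.eye(n) + tau0 ** 2 * np.ones((n, n))
    logml = float(stats.multivariate_normal.logpdf(
        y, mean=np.full(n, mu0), cov=cov))

    def log_post(theta):
        th = np.asarray(theta)[..., 0]
        ll = (-0.5 * ((y[None, :] - th[:, None]) / sigma) ** 2
              - np.log(sigma) - 0.5 * np.log(2 * np.pi))
        lp = (-0.5 * ((th - mu0) / tau0) ** 2 - np.log(tau0)
              - 0.5 * np.log(2 * np.pi))
        return ll.sum(axis=-1) + lp

    draws = rng.normal(m_post, np.sqrt(v_post), (4, n_draws, 1))
    res = bridge_log_marginal(draws, log_post, BridgeConfig(seed=seed + 1))
    return {"estimate": res.logml, "closed_form": logml,
            "abs_error": abs(res.logml - logml)}


_NULL_TRUTH = {**STUDY_GROUP_MEANS, "delta_mu_np": 0.0, "delta_mu_nc": 0.0,
               "delta_kappa_np": 0.0, "delta_kappa_nc": 0.0}


def _fit_sim_cohort(truth: GroupParams, n_per_condition, seed: int,
                    mcmc: MCMCConfig, fixation_mean: float = 30.0):
    cfg = SimulationConfig(truth=truth, n_per_condition=n_per_condition,
                           fixation_count_mean=fixation_mean, seed=seed)
    seqs, _ = simulate_fixation_cohort(cfg)
    data = FixationData.from_sequences(seqs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(data, "h1", PriorSpec(), mcmc), data


def recovery_study(seed: int = 0, n_reps: int = 20,
                   n_per_condition=(54, 55, 50)) -> dict:
    """Coverage of the generating group parameters over seeded replicates.

    Cohorts are simulated at the fitted group-level means of the study
    (reference concentration 1.724, process shift -0.466) at half the
    study's group sizes, and the condition-effects model is refitted to
    each; the 95% central posterior interval should cover the generating
    value at nominal rate.
    """
    truth = GroupParams(**STUDY_GROUP_MEANS)
    seeds = _spawn_seeds(seed, n_reps)
    targets = {"alpha_kappa": truth.alpha_kappa,
               "delta_kappa_np": truth.delta_kappa_np}
    covered = {k: 0 for k in targets}
    means = {k: [] for k in targets}
    for s in seeds:
        fit, _ = _fit_sim_cohort(truth, n_per_condition, s,
                                 MCMCConfig(seed=s + 1))
        summ = posterior_summary(fit)
        for k, tv in targets.items():
            if summ.loc[k, "2.5%"] <= tv <= summ.loc[k, "97.5%"]:
                covered[k] += 1
            means[k].append(summ.loc[k, "mean"])
    return {
        "n_reps": n_reps,
        "covered": covered,
        "coverage_pct": {k: 100.0 * v / n_reps for k, v in covered.items()},
        "posterior_mean": {k: float(np.mean(v)) for k, v in means.items()},
        "truth": targets,
    }


def null_recovery_study(seed: int = 1000, n_reps: int = 20,
                        n_per_condition=(54, 55, 50)) -> dict:
    """Cohorts with no condition effects: delta posteriors center on zero.

    A replicate counts as centered when |posterior mean| < 2 posterior SD
    for the process concentration shift.
    """
    truth = GroupParams(**_NULL_TRUTH)
    seeds = _spawn_seeds(seed, n_reps)
    centered = 0
    for s in seeds:
        fit, _ = _fit_sim_cohort(truth, n_per_condition, s,
                                 MCMCConfig(seed=s + 1))
        summ = posterior_summary(fit)
        if abs(summ.loc["delta_kappa_np", "mean"]) < \
                2.0 * summ.loc["delta_kappa_np", "sd"]:
            centered += 1
    return {"n_reps": n_reps, "centered": centered,
            "centered_pct": 100.0 * centered / n_reps}


def evidence_direction_study(seed: int = 0, n_reps: int = 5,
                             n_per_condition=(90, 90, 90),
                             null_truth: bool = False) -> dict:
    """Median log BF10 across refits on simulated cohorts.

    With the study's fitted group means as truth the evidence should
    favour the condition-effects model (median log BF10 > 0); with all
    deltas zeroed it should favour the null (median < 0).
    """
    truth = GroupParams(**(_NULL_TRUTH if null_truth else STUDY_GROUP_MEANS))
    log_bfs = []
    for s in _spawn_seeds(seed, n_reps):
        cfg = SimulationConfig(truth=truth, n_per_condition=n_per_condition,
                               seed=s)
        seqs, _ = simulate_fixation_cohort(cfg)
        data = FixationData.from_sequences(seqs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = fit_model(data, "h1", PriorSpec(),
                           MCMCConfig(seed=s + 1, warmup=1500, iters=1500))
            f0 = fit_model(data, "h0", PriorSpec(),
                           MCMCConfig(seed=s + 2, warmup=1500, iters=1500))
        lm1 = model_log_marginal(f1, BridgeConfig(seed=s + 3), max_eval=1000)
        lm0 = model_log_marginal(f0, BridgeConfig(seed=s + 4), max_eval=1000)
        log_bfs.append(float(lm1.logml - lm0.logml))
    return {"log_bf10": log_bfs, "median_log_bf10": float(np.median(log_bfs)),
            "n_reps": n_reps}
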