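"""End-to-end orchestration: configuration, simulation studies, analysis.

Two entry points mirror how the package is used.  ``run_recovery_study``
is the self-contained simulation harness: it generates synthetic cohorts
at known group-level truth, pushes them through preprocessing and both
model fits, compares the models, and reports interval coverage of the
truth.  ``run_analysis`` runs the full analysis chain on a directory of
trajectory logs plus a cohort manifest: exclusions, fixation extraction,
Likert MANOVA with post-hoc contrasts, movement ANCOVA, the hierarchical
von Mises fits with summary tables, Bayes-factor stability, and figure /
dwell-map exports.

Every output directory receives a ``report.json`` embedding the seed and
a hash of the configuration, so identical configurations reproduce
identical numeric outputs.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from vantage import metrics
from vantage.circular import (FixationData, MCMCConfig, PriorSpec, fit_model,
                              posterior_summary)
from vantage.comparison import BridgeConfig, bayes_factor_stability
from vantage.preprocess import (ExclusionConfig, apply_exclusions,
                                detect_fixations, fixation_table)
from vantage.sessions import (Cohort, read_cohort_manifest, read_trajectory_tsv,
                              write_cohort_manifest, write_trajectory_tsv)
from vantage.simulate import SimulationConfig, simulate_cohort

log = logging.getLogger("vantage")

__all__ = ["RunConfig", "run_recovery_study", "run_analysis",
           "save_config", "load_config", "config_hash",
           "write_cohort_dir", "read_cohort_dir"]


@dataclass
class RunConfig:
    """Flat, file-round-trippable run configuration.

    The protocol constants keep their study values as defaults: 500 ms
    minimum dwell, 10 records/s minimum rate, 100 s main trial.
    """

    seed: int = 0
    out_dir: str = "results"
    min_dwell_ms: float = 500.0
    min_rate: float = 10.0
    d_max: float = 0.0            # 0 -> relative default (10x initial distance)
    min_travel: float = 0.0       # 0 -> relative default (1% initial distance)
    eps: float = 0.0              # stationarity tolerance, scene units
    chains: int = 4
    warmup: int = 1000
    iters: int = 1000
    bf_repeats: int = 10
    recovery_reps: int = 2
    n_per_condition: int = 20
    alpha_mu_scale: float = 1.0
    alpha_kappa_scale: float = 5.0
    delta_scale: float = 0.3
    delta_df: float = 1.0
    sigma_mu_scale: float = 2.0
    sigma_kappa_scale: float = 2.0

    def __post_init__(self):
        for name in ("min_dwell_ms", "min_rate", "chains", "warmup", "iters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def priors(self) -> PriorSpec:
        return PriorSpec(
            alpha_mu_scale=self.alpha_mu_scale,
            alpha_kappa_scale=self.alpha_kappa_scale,
            delta_scale=self.delta_scale,
            delta_df=self.delta_df,
            sigma_mu_scale=self.sigma_mu_scale,
            sigma_kappa_scale=self.sigma_kappa_scale,
        )

    def mcmc(self, seed: int | None = None) -> MCMCConfig:
        return MCMCConfig(chains=self.chains, warmup=self.warmup,
                          iters=self.iters,
                          seed=self.seed if seed is None else seed)

    def exclusions(self) -> ExclusionConfig:
        return ExclusionConfig(
            d_max=self.d_max or None, min_travel=self.min_travel or None,
            min_rate=self.min_rate)


def save_config(cfg: RunConfig, path) -> None:
    cp = configparser.ConfigParser()
    cp["vantage"] = {k: repr(v) for k, v in dataclasses.asdict(cfg).items()}
    with open(path, "w") as fh:
        cp.write(fh)


def load_config(path) -> RunConfig:
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise FileNotFoundError(path)
    kwargs = {}
    defaults = RunConfig()
    for f in dataclasses.fields(RunConfig):
        if f.name not in cp["vantage"]:
            continue
        raw = cp["vantage"][f.name].strip("'\"")
        kind = type(getattr(defaults, f.name))
        kwargs[f.name] = raw if kind is str else kind(raw)
    return RunConfig(**kwargs)


def config_hash(cfg: RunConfig) -> str:
    """Hash of the scientific configuration (paths excluded)."""
    payload = {k: v for k, v in dataclasses.asdict(cfg).items()
               if k != "out_dir"}
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()
                        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# cohort directory I/O


def write_cohort_dir(cohort: Cohort, directory) -> Path:
    """Persist a cohort as manifest.csv plus one TSV log per participant."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_cohort_manifest(cohort, directory / "manifest.csv")
    for s in cohort.sessions:
        write_trajectory_tsv(s, directory / f"{s.participant_id}.tsv")
    return directory


def read_cohort_dir(directory) -> Cohort:
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"missing cohort manifest: {manifest}")
    shell = read_cohort_manifest(manifest)
    sessions = []
    for s in shell.sessions:
        tsv = directory / f"{s.participant_id}.tsv"
        if not tsv.exists():
            raise FileNotFoundError(f"missing trajectory log: {tsv}")
        sessions.append(read_trajectory_tsv(tsv, s.participant_id, s.condition))
    return Cohort(sessions=sessions, likert=shell.likert)


# ---------------------------------------------------------------------------
# simulation-based recovery study


def run_recovery_study(cfg: RunConfig | None = None) -> dict:
    """Simulate, preprocess, fit both models, compare; report coverage.

    Each repetition draws a fresh cohort at the default group-level truth,
    runs the full preprocessing chain, fits H0 and H1, computes one
    bridge-sampled Bayes factor, and checks whether the 95% central
    posterior intervals cover the generating group parameters.
    """
    cfg = cfg or RunConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.recovery_reps)
    truth_names = ("alpha_mu", "alpha_kappa", "delta_kappa_np", "sigma_mu",
                   "sigma_kappa")
    rows = []
    log_bfs = []
    for rep, seed_seq in enumerate(rng_seeds):
        s_sim, s_fit0, s_fit1, s_bridge = [int(s.generate_state(1)[0] >> 1)
                                           for s in seed_seq.spawn(4)]
        sim_cfg = SimulationConfig(
            n_per_condition=(cfg.n_per_condition,) * 3, seed=s_sim)
        cohort, truth = simulate_cohort(sim_cfg)
        retained, report = apply_exclusions(cohort, cfg.exclusions())
        seqs = [detect_fixations(s, cfg.min_dwell_ms, cfg.eps)
                for s in retained.sessions]
        data = FixationData.from_sequences(seqs)
        log.info("rep %d: %d participants, %d excluded, %d fixations",
                 rep, data.n_participants, report.n_excluded, int(data.n.sum()))
        fit1 = fit_model(data, "h1", cfg.priors(), cfg.mcmc(s_fit1))
        fit0 = fit_model(data, "h0", cfg.priors(), cfg.mcmc(s_fit0))
        from vantage.comparison import model_log_marginal
        lm1 = model_log_marginal(fit1, BridgeConfig(seed=s_bridge))
        lm0 = model_log_marginal(fit0, BridgeConfig(seed=s_bridge + 1))
        log_bfs.append(lm1.logml - lm0.logml)
        summ = posterior_summary(fit1)
        for name in truth_names:
            tv = truth["group"][name]
            lo, hi = summ.loc[name, "2.5%"], summ.loc[name, "97.5%"]
            rows.append({"rep": rep, "parameter": name, "truth": tv,
                         "lo": lo, "mean": summ.loc[name, "mean"], "hi": hi,
                         "covered": bool(lo <= tv <= hi),
                         "max_rhat": fit1.convergence.max_rhat})
    coverage = pd.DataFrame(rows)
    coverage.to_csv(out / "recovery_coverage.csv", index=False)
    med = float(np.median(log_bfs))
    report = {
        "config_hash": config_hash(cfg), "seed": cfg.seed,
        "reps": cfg.recovery_reps,
        "coverage_rate": float(coverage["covered"].mean()),
        "median_log_bf10": med,
        "evidence_direction": "H1-favored" if med > 0 else "H0-favored",
        "log_bf10": [float(b) for b in log_bfs],
        "priors": cfg.priors().to_dict(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


# ---------------------------------------------------------------------------
# dataset analysis


def run_analysis(data_dir, cfg: RunConfig | None = None,
                 mesh_path=None) -> dict:
    """Full analysis of a cohort directory; writes all artifact tables."""
    cfg = cfg or RunConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort_dir(data_dir)
    report: dict = {"config_hash": config_hash(cfg), "seed": cfg.seed,
                    "n_input": len(cohort), "priors": cfg.priors().to_dict()}

    # Likert MANOVA on the full cohort
    if not cohort.likert.empty:
        ids = [s.participant_id for s in cohort.sessions]
        Y = cohort.likert.loc[ids].to_numpy()
        groups = np.array([int(s.condition) for s in cohort.sessions])
        manova = metrics.manova_pillai(Y, groups)
        pairs = [(0, 1), (0, 2), (1, 2)]
        posthoc = metrics.posthoc_contrasts(Y, groups, pairs)
        metrics.results_table([manova, *posthoc]).to_csv(
            out / "likert_manova.csv", index=False)
        report["manova"] = {"T": manova.statistic, "F": manova.f_value,
                            "df": [manova.df1, manova.df2], "p": manova.p_value}

    # exclusions
    retained, excl = apply_exclusions(cohort, cfg.exclusions())
    excl.to_frame().to_csv(out / "exclusions.csv", index=False)
    for crit, idlist in excl.flagged.items():
        for pid in idlist:
            log.info("excluded %s by criterion %s", pid, crit)
    report["exclusions"] = {"excluded": excl.n_excluded,
                            "retained": excl.n_retained,
                            "counts": excl.counts}

    # movement ANCOVA
    summaries = [metrics.movement_summary(s) for s in retained.sessions]
    pd.DataFrame([dataclasses.asdict(m) for m in summaries]).to_csv(
        out / "movement.csv", index=False)
    y = np.array([m.d_total for m in summaries])
    grp = np.array([m.condition for m in summaries])
    cov = np.array([m.d_cov for m in summaries])
    anc = metrics.ancova_oneway(y, grp, cov)
    anc_posthoc = metrics.posthoc_contrasts(
        y, grp, [(0, 1), (0, 2), (1, 2)], covariate=cov)
    metrics.results_table([anc.group, anc.covariate, *anc_posthoc]).to_csv(
        out / "movement_ancova.csv", index=False)
    report["ancova"] = {"F": anc.group.f_value,
                        "df": [anc.group.df1, anc.group.df2],
                        "p": anc.group.p_value}
    report["d_total_mean_by_condition"] = {
        str(c): float(y[grp == c].mean()) for c in np.unique(grp)}

    # fixations and the hierarchical model
    seqs = [detect_fixations(s, cfg.min_dwell_ms, cfg.eps)
            for s in retained.sessions]
    fixation_table(seqs).to_csv(out / "fixations.csv", index=False)
    data = FixationData.from_sequences(seqs)
    fits = {}
    for tag in ("h0", "h1"):
        fit = fit_model(data, tag, cfg.priors(),
                        cfg.mcmc(cfg.seed + (1 if tag == "h1" else 0)))
        fits[tag] = fit
        summ = posterior_summary(fit)
        summ.to_csv(out / f"posterior_{tag}.csv")
        report[f"{tag}_max_rhat"] = fit.convergence.max_rhat
        report[f"{tag}_summary"] = {k: float(v) for k, v in
                                    summ["mean"].items()}
        if not fit.convergence.converged:
            report[f"{tag}_convergence_flag"] = str(fit.convergence)

    # Bayes-factor stability
    comparison = bayes_factor_stability(
        data, cfg.priors(), cfg.mcmc(), BridgeConfig(),
        n_repeats=cfg.bf_repeats, seed=cfg.seed)
    pd.DataFrame({
        "logml_h0": comparison.logml_h0, "logml_h1": comparison.logml_h1,
        "bf10": comparison.bf10,
    }).to_csv(out / "bayes_factors.csv", index=False)
    report["bf10"] = {"min": comparison.bf_min, "max": comparison.bf_max,
                      "median_log": comparison.median_log_bf10,
                      "n_invalid": comparison.n_invalid}

    _export_figures(data, fits, out)

    if mesh_path is not None:
        from vantage.surface import accumulate_dwell, dwell_map_table, load_mesh
        mesh = load_mesh(mesh_path)
        dmap = accumulate_dwell(retained.sessions, mesh)
        dwell_map_table(dmap).to_csv(out / "dwell_map.csv", index=False)
        report["dwell_map_voxels"] = int(dmap.occupied().sum())

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _export_figures(data: FixationData, fits: dict, out: Path) -> None:
    """ECDF of participant concentrations and polar angle density.

    Best-effort visual summaries; failures are logged, never fatal.
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fit = fits["h1"]
        _, kappa = fit.participant_draws()
        kappa_mean = kappa.mean(axis=(0, 1))
        fig, axes = plt.subplots(1, 2, figsize=(10, 4),
                                 subplot_kw=None)
        ax = axes[0]
        for c, color in zip((0, 1, 2), ("tab:green", "tab:red", "tab:blue")):
            vals = np.sort(kappa_mean[data.condition == c])
            if len(vals) == 0:
                continue
            ax.step(vals, np.linspace(0, 1, len(vals)), color=color,
                    label=("narrative", "process", "creator")[c])
        ax.set_xlabel("posterior mean kappa_i")
        ax.set_ylabel("ECDF")
        ax.legend()
        ax = axes[1]
        theta_grid = np.linspace(-np.pi, np.pi, 256)
        mu_bar = np.arctan2(data.S, data.C)
        for c, color in zip((0, 1, 2), ("tab:green", "tab:red", "tab:blue")):
            sel = data.condition == c
            if not sel.any():
                continue
            dens = np.zeros_like(theta_grid)
            from vantage.circular import vonmises_logpdf
            kap = np.clip(kappa_mean[sel], 0.0, None)
            for m, k in zip(mu_bar[sel], kap):
                dens += np.exp(vonmises_logpdf(theta_grid, m, k))
            ax.plot(theta_grid, dens / sel.sum(), color=color)
        ax.set_xlabel("view-angle (rad)")
        ax.set_ylabel("mean fitted density")
        fig.tight_layout()
        fig.savefig(out / "figures.png", dpi=120)
        plt.close(fig)
    except Exception as exc:  # pragma: no cover - best effort only
        log.warning("figure export failed: %s", exc)
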