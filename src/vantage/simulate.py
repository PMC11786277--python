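"""Synthetic-cohort generation with the structure the analysis assumes.

The simulator works top-down through the same hierarchy the model fits:
per participant it draws (mu_i, kappa_i) from the condition's group
distribution, a fixation count and dwell times, then fixation view-angles
from the participant's von Mises distribution.  The planned fixations are
rendered into an orbit-camera trajectory — exact-repeat frames during each
dwell, connected by constant-angular-speed orbit arcs with linear radius
interpolation — sampled at the logging-rate regime, so that the full
preprocessing chain (rate exclusion, fixation detection, view-angle
computation) can be exercised and inverted.

Defaults are the study's conditions: group sizes 108/110/99 and
group-level parameters at the fitted posterior means of the
condition-effects model (reference concentration 1.724 with a -0.466
process shift, mean direction 0.344 with small shifts, spreads 0.385 /
0.820).  Dwell times are log-normal (median 900 ms, 0.6 log-units) and
fixation counts negative-binomial (mean 30); the study does not report
these distributions, so they are package choices, configurable and
recorded in every ground-truth sidecar.  Practice-phase movement is
generated correlated (rho = 0.4) with main-phase movement so the ANCOVA
covariate is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from vantage.circular import GroupParams
from vantage.preprocess import FixationSequence, wrap_angle
from vantage.sessions import Cohort, Condition, LIKERT_DIMENSIONS, Session

__all__ = [
    "OrbitConfig", "RateConfig", "SimulationConfig", "sample_vonmises",
    "simulate_fixation_cohort", "simulate_cohort", "render_trajectory",
    "make_exclusion_cohort",
]


#: Group-level truth used by default: posterior means of the fitted
#: condition-effects model on the study data.
STUDY_GROUP_MEANS = dict(
    alpha_mu=0.344, delta_mu_np=-0.042, delta_mu_nc=-0.074,
    alpha_kappa=1.724, delta_kappa_np=-0.466, delta_kappa_nc=0.003,
    sigma_mu=0.385, sigma_kappa=0.820,
)

#: Study group sizes before exclusions (narrative, process, creator).
STUDY_GROUP_SIZES = (108, 110, 99)


@dataclass(frozen=True)
class OrbitConfig:
    """Orbit-camera geometry for rendering planned fixations."""

    target: tuple = (0.0, 1.0, 0.0)
    elevation: float = 1.2            # camera height above ground, scene units
    angular_speed: float = 1.2       # rad/s during transit arcs
    radial_speed: float = 2.0        # units/s for radius changes


@dataclass(frozen=True)
class RateConfig:
    """Logging-rate regime: nominal browser rate with random frame drops."""

    nominal_hz: float = 60.0
    dropout_p: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.nominal_hz <= 60.0):
            raise ValueError("nominal rate must be in (0, 60] Hz")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout probability must be in [0, 1)")


@dataclass
class SimulationConfig:
    """Ground truth and sampling regime for a synthetic cohort."""

    truth: GroupParams = field(
        default_factory=lambda: GroupParams(**STUDY_GROUP_MEANS))
    n_per_condition: tuple = STUDY_GROUP_SIZES
    fixation_count_mean: float = 30.0
    fixation_count_dispersion: float = 10.0   # negative-binomial shape r
    dwell_median_ms: float = 900.0
    dwell_log_sd: float = 0.6
    radius_range: tuple = (3.0, 8.0)
    orbit: OrbitConfig = field(default_factory=OrbitConfig)
    rate: RateConfig = field(default_factory=RateConfig)
    main_duration_ms: float = 100_000.0
    practice_duration_ms: float = 30_000.0
    practice_corr: float = 0.4
    likert_mean: tuple = (4.2, 4.0, 3.8, 4.0, 3.6, 4.1, 3.2, 4.3, 3.0)
    likert_sd: float = 1.2
    likert_corr: float = 0.3
    #: additive condition shifts, direction-of-effect only (small):
    #: process raises empathy and imagination; creator empathy and interest.
    likert_shift_process: dict = field(
        default_factory=lambda: {"empathy": 0.45, "imagination": 0.30})
    likert_shift_creator: dict = field(
        default_factory=lambda: {"empathy": 0.30, "interest": 0.30})
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.n_per_condition):
            raise ValueError("all condition sizes must be positive")


# ---------------------------------------------------------------------------
# primitive draws


def sample_vonmises(mu: float, kappa: float, n: int, seed=None) -> np.ndarray:
    """Draw n von Mises angles in (-pi, pi], seeded-reproducible.

    Uses the Best-Fisher rejection sampler (NumPy's generator algorithm);
    kappa = 0 reduces to the circular uniform.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if n < 1:
        raise ValueError("need n >= 1 draws")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return wrap_angle(rng.vonmises(mu, kappa, size=n))


def _sample_truncnorm_nonneg(loc, scale, rng: np.random.Generator) -> np.ndarray:
    """Vectorised rejection sampling from Normal(loc, scale) on [0, inf)."""
    loc = np.asarray(loc, dtype=float)
    out = np.full(loc.shape, -1.0)
    pending = np.ones(loc.shape, dtype=bool)
    for _ in range(1000):
        if not pending.any():
            break
        draw = rng.normal(loc, scale)
        take = pending & (draw >= 0.0)
        out[take] = draw[take]
        pending &= ~take
    if pending.any():  # far-negative locations: sample the tail directly
        u = rng.random(int(pending.sum()))
        from scipy import stats
        a = (0.0 - loc[pending]) / scale
        out[pending] = stats.truncnorm.ppf(u, a, np.inf, loc=loc[pending], scale=scale)
    return out


# ---------------------------------------------------------------------------
# model-level (fast) cohort


def _participant_conditions(n_per_condition) -> np.ndarray:
    return np.concatenate([
        np.full(n, int(c)) for n, c in zip(n_per_condition, Condition)])


def simulate_fixation_cohort(cfg: SimulationConfig | None = None, rng=None):
    """Draw fixation sequences directly from the hierarchy (no rendering).

    Returns ``(sequences, truth)`` where truth records the group
    parameters and every participant's (mu_i, kappa_i).  This is the fast
    path for parameter-recovery studies; :func:`simulate_cohort` renders
    the same structure into full trajectory logs.
    """
    cfg = cfg or SimulationConfig()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        cfg.seed if rng is None else rng)
    cond = _participant_conditions(cfg.n_per_condition)
    P = len(cond)
    t = cfg.truth
    mu_i = rng.normal(t.alpha_mu_of(cond), t.sigma_mu)
    kappa_i = _sample_truncnorm_nonneg(t.alpha_kappa_of(cond), t.sigma_kappa, rng)
    r = cfg.fixation_count_dispersion
    p_nb = r / (r + cfg.fixation_count_mean)
    n_fix = np.maximum(rng.negative_binomial(r, p_nb, size=P), 1)
    sequences = []
    for i in range(P):
        theta = sample_vonmises(mu_i[i], kappa_i[i], int(n_fix[i]), rng)
        dwell = cfg.dwell_median_ms * np.exp(
            rng.normal(0.0, cfg.dwell_log_sd, int(n_fix[i])))
        cam = np.zeros((int(n_fix[i]), 3))
        sequences.append(FixationSequence(f"p{i:04d}", int(cond[i]),
                                          theta, dwell, cam))
    truth = {"group": asdict(t), "condition": cond, "mu_i": mu_i,
             "kappa_i": kappa_i, "n_fix": n_fix}
    return sequences, truth


# ---------------------------------------------------------------------------
# trajectory rendering


def render_trajectory(plan, orbit: OrbitConfig | None = None,
                      rate: RateConfig | None = None, rng=None,
                      phase: str = "main", pad_to_ms: float | None = None):
    """Render a fixation plan into frame arrays ``(t, cam, tgt, phase)``.

    ``plan`` is a sequence of ``(theta, radius, dwell_ms)`` triples.  The
    camera holds each planned position bit-exactly for its dwell, and
    moves between fixations along the orbit sphere at constant angular
    speed (shortest arc) with linear radius interpolation.  Frame times
    follow the rate regime; with ``pad_to_ms`` the final hold is extended
    so the phase spans the full trial duration.
    """
    orbit = orbit or OrbitConfig()
    rate = rate or RateConfig()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    plan = [(float(th), float(r), float(dw)) for th, r, dw in plan]
    if not plan:
        raise ValueError("fixation plan is empty")

    # segment list: (duration_ms, kind, (theta0, r0, theta1, r1))
    segments = []
    prev = None
    for theta, radius, dwell in plan:
        if prev is not None:
            th0, r0 = prev
            dth = wrap_angle(theta - th0)
            dur = 1000.0 * max(abs(dth) / orbit.angular_speed,
                               abs(radius - r0) / orbit.radial_speed)
            if dur > 0:
                segments.append((dur, "transit", (th0, r0, th0 + dth, radius)))
        segments.append((dwell, "hold", (theta, radius, theta, radius)))
        prev = (theta, radius)
    total = sum(s[0] for s in segments)
    if pad_to_ms is not None and total < pad_to_ms:
        dur, kind, geo = segments[-1]
        segments[-1] = (dur + (pad_to_ms - total), kind, geo)
        total = pad_to_ms

    dt = 1000.0 / rate.nominal_hz
    bounds = np.cumsum([0.0] + [s[0] for s in segments])
    # regular grid with the frame following each segment boundary snapped
    # onto it: every hold starts bit-exactly on a logged frame while the
    # frame count (hence the record rate) stays at the nominal cap
    times = np.arange(0.0, total, dt)
    idx = np.searchsorted(times, bounds[:-1], side="left")
    inside = idx < len(times)
    times[idx[inside]] = bounds[:-1][inside]
    if rate.dropout_p > 0.0:
        keep = rng.random(len(times)) >= rate.dropout_p
        keep[0] = keep[-1] = True
        times = times[keep]
    seg_idx = np.clip(np.searchsorted(bounds, times, side="right") - 1,
                      0, len(segments) - 1)

    tgt = np.asarray(orbit.target, dtype=float)
    cam = np.empty((len(times), 3))
    for k, (dur, kind, (th0, r0, th1, r1)) in enumerate(segments):
        m = seg_idx == k
        if not m.any():
            continue
        if kind == "hold":
            cam[m] = _orbit_pos(th0, r0, tgt, orbit.elevation)
        else:
            frac = (times[m] - bounds[k]) / dur
            th = th0 + frac * (th1 - th0)
            rr = r0 + frac * (r1 - r0)
            cam[m] = np.stack([tgt[0] + rr * np.sin(th),
                               np.full(len(th), tgt[1] + orbit.elevation),
                               tgt[2] + rr * np.cos(th)], axis=1)
    t_ms = np.round(times).astype(np.int64)
    uniq = np.concatenate([[True], np.diff(t_ms) > 0]) if len(t_ms) else np.array([], bool)
    t_ms, cam = t_ms[uniq], cam[uniq]
    tgt_arr = np.tile(tgt, (len(t_ms), 1))
    phase_arr = np.full(len(t_ms), phase, dtype="U8")
    return t_ms, cam, tgt_arr, phase_arr


def _orbit_pos(theta, radius, tgt, elevation):
    return np.array([tgt[0] + radius * np.sin(theta),
                     tgt[1] + elevation,
                     tgt[2] + radius * np.cos(theta)])


# ---------------------------------------------------------------------------
# full cohort with trajectory logs


def simulate_cohort(cfg: SimulationConfig | None = None):
    """Simulate a full cohort with practice and main trajectory logs.

    Returns ``(cohort, truth)``; the truth dict carries the group
    parameters, per-participant (mu_i, kappa_i), the planned fixation
    schedule, and the configuration, suitable for a JSON sidecar.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    sequences, truth = simulate_fixation_cohort(cfg, rng)
    P = len(sequences)

    # plan main phases, tracking arc length for the practice correlation
    plans = []
    arc_log = np.empty(P)
    budget = 0.97 * cfg.main_duration_ms
    n_rescheduled = 0
    for i, seq in enumerate(sequences):
        radii = rng.uniform(*cfg.radius_range, seq.n_events)
        plan = list(zip(seq.theta, radii, seq.dwell))
        total = _plan_duration(plan, cfg.orbit)
        if total > budget:
            n_rescheduled += 1
            scale = budget / total
            plan = [(th, r, dw * scale) for th, r, dw in plan]
            # drop sub-threshold dwells created by the rescale
            kept = [p for p in plan if p[2] >= 520.0] or plan[:1]
            plan = kept
        plans.append(plan)
        arc = sum(abs(wrap_angle(b[0] - a[0])) * 0.5 * (a[1] + b[1])
                  for a, b in zip(plan[:-1], plan[1:]))
        arc_log[i] = np.log(max(arc, 1e-3))
    if n_rescheduled:
        warnings.warn(f"{n_rescheduled} fixation schedule(s) exceeded the "
                      "trial length and were rescaled", stacklevel=2)

    # practice sweep correlated with main-phase movement
    z_main = (arc_log - arc_log.mean()) / max(arc_log.std(), 1e-9)
    rho = cfg.practice_corr
    z_pr = rho * z_main + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(P)

    sessions = []
    likert_rows = {}
    for i, seq in enumerate(sequences):
        t_m, cam_m, tgt_m, ph_m = render_trajectory(
            plans[i], cfg.orbit, cfg.rate, rng, phase="main",
            pad_to_ms=cfg.main_duration_ms)
        pr_plan = _practice_plan(z_pr[i], cfg, rng)
        t_p, cam_p, tgt_p, ph_p = render_trajectory(
            pr_plan, cfg.orbit, cfg.rate, rng, phase="practice",
            pad_to_ms=cfg.practice_duration_ms)
        sessions.append(Session(
            seq.participant_id, seq.condition,
            np.concatenate([t_p, t_m]),
            np.concatenate([cam_p, cam_m]),
            np.concatenate([tgt_p, tgt_m]),
            np.concatenate([ph_p, ph_m]),
        ))
        likert_rows[seq.participant_id] = _likert_draw(seq.condition, cfg, rng)

    likert = pd.DataFrame.from_dict(likert_rows, orient="index",
                                    columns=list(LIKERT_DIMENSIONS))
    cohort = Cohort(sessions=sessions, likert=likert)
    truth["plans"] = plans
    truth["config"] = cfg
    return cohort, truth


def _plan_duration(plan, orbit: OrbitConfig) -> float:
    dur = sum(p[2] for p in plan)
    for a, b in zip(plan[:-1], plan[1:]):
        dth = abs(wrap_angle(b[0] - a[0]))
        dur += 1000.0 * max(dth / orbit.angular_speed,
                            abs(b[1] - a[1]) / orbit.radial_speed)
    return dur


def _practice_plan(z: float, cfg: SimulationConfig, rng: np.random.Generator):
    """A short wander on the dummy model whose sweep scales with exp(z/2)."""
    k = 5
    sweep = 2.0 * np.exp(0.5 * z)
    steps = rng.uniform(0.3, 1.0, k - 1)
    steps *= sweep / steps.sum()
    signs = rng.choice([-1.0, 1.0], k - 1)
    thetas = np.concatenate([[0.0], np.cumsum(steps * signs)])
    radii = rng.uniform(*cfg.radius_range, k)
    dwells = 700.0 * np.exp(rng.normal(0.0, 0.4, k)) + 520.0
    return list(zip(wrap_angle(thetas), radii, dwells))


def _likert_draw(condition: int, cfg: SimulationConfig, rng: np.random.Generator):
    p = len(LIKERT_DIMENSIONS)
    mean = np.asarray(cfg.likert_mean, dtype=float).copy()
    shift = (cfg.likert_shift_process if condition == 1
             else cfg.likert_shift_creator if condition == 2 else {})
    for dim, dv in shift.items():
        mean[LIKERT_DIMENSIONS.index(dim)] += dv
    cov = cfg.likert_sd ** 2 * (
        (1.0 - cfg.likert_corr) * np.eye(p) + cfg.likert_corr * np.ones((p, p)))
    return np.clip(rng.multivariate_normal(mean, cov), 1.0, 7.0)


# ---------------------------------------------------------------------------
# engineered exclusion cohort


def make_exclusion_cohort(n_total: int = 317, n_flagged=(3, 17, 37),
                          n_overlap: int = 1, seed: int = 0,
                          nominal_hz: float = 15.0,
                          low_hz: float = 8.0) -> Cohort:
    """Construct a cohort in which the three criteria flag known counts.

    ``n_flagged`` gives (too-far, too-short-travel, low-rate) counts and
    ``n_overlap`` participants carry both the short-travel and low-rate
    flags, so the excluded union is ``sum(n_flagged) - n_overlap``.
    Trajectories are lightweight random walks around the target — enough
    structure for every exclusion statistic, cheap enough for a
    317-participant cohort in well under a second.
    """
    n_far, n_short, n_low = n_flagged
    if n_overlap > min(n_short, n_low):
        raise ValueError("overlap cannot exceed the overlapping criteria counts")
    if n_far + n_short + n_low - n_overlap > n_total:
        raise ValueError("flagged counts exceed cohort size")
    rng = np.random.default_rng(seed)
    sizes = _study_sizes(n_total)
    cond = _participant_conditions(sizes)
    ids = [f"p{i:04d}" for i in range(n_total)]

    # flag assignment: shuffled ids; overlap ids carry two flags
    order = rng.permutation(n_total)
    far_ids = set(order[:n_far])
    short_ids = set(order[n_far:n_far + n_short])
    low_ids = set(list(order[n_far + n_short:n_far + n_short + n_low - n_overlap])
                  + list(order[n_far:n_far + n_overlap]))

    tgt0 = np.array([0.0, 1.0, 0.0])
    start = np.array([0.0, 2.0, 5.0])
    duration_ms = 100_000
    sessions = []
    likert_rows = {}
    cfg = SimulationConfig()
    for i in range(n_total):
        hz = low_hz if i in low_ids else nominal_hz
        n_frames = int(duration_ms / 1000.0 * hz) + 1
        t = np.linspace(0, duration_ms, n_frames).astype(np.int64)
        if i in short_ids:
            steps = rng.normal(0.0, 1e-5, (n_frames - 1, 3))
        else:
            steps = rng.normal(0.0, 0.05, (n_frames - 1, 3))
        cam = start + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        if i in far_ids:
            j = rng.integers(1, n_frames - 1)
            cam[j] = tgt0 + np.array([0.0, 0.0, 120.0])  # beyond 10x initial
        tgt = np.tile(tgt0, (n_frames, 1))
        phase = np.full(n_frames, "main", dtype="U8")
        # small practice block for the covariate
        t_p = np.arange(0, 10_000, 100, dtype=np.int64)
        cam_p = start + 0.02 * np.cumsum(rng.standard_normal((len(t_p), 3)), axis=0)
        sessions.append(Session(
            ids[i], int(cond[i]),
            np.concatenate([t_p, t]),
            np.vstack([cam_p, cam]),
            np.vstack([np.tile(tgt0, (len(t_p), 1)), tgt]),
            np.concatenate([np.full(len(t_p), "practice", dtype="U8"), phase]),
        ))
        likert_rows[ids[i]] = _likert_draw(int(cond[i]), cfg, rng)
    likert = pd.DataFrame.from_dict(likert_rows, orient="index",
                                    columns=list(LIKERT_DIMENSIONS))
    return Cohort(sessions=sessions, likert=likert)


def _study_sizes(n_total: int) -> tuple:
    """Split n_total across conditions in the study's 108:110:99 proportions."""
    base = np.array(STUDY_GROUP_SIZES, dtype=float)
    sizes = np.floor(base / base.sum() * n_total).astype(int)
    sizes[0] += n_total - sizes.sum()
    return tuple(int(s) for s in sizes)
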