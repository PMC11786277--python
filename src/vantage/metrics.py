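"""Movement statistics and the classical inferential layer.

``d_total`` is the natural log of the summed Euclidean distance between
temporally adjacent camera positions in the main viewing phase; the same
statistic on the practice phase, ``d_cov``, enters the group comparison as
an ANCOVA covariate to absorb a participant's general tendency to move.

The multivariate layer tests whether the pattern of the nine Likert
dimensions differs across instruction conditions with Pillai's trace,
T = sum lambda/(1+lambda) over the eigenvalues of E^-1 H, using the
standard F approximation.  Both ANCOVA and MANOVA are computed directly
from least squares / eigen decompositions so that every sum of squares is
inspectable; group effects use Type-III-style (partial) sums of squares,
appropriate for the unequal group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from vantage.sessions import Session

__all__ = [
    "MovementSummary", "AnovaFamilyResult", "AncovaResult",
    "DegenerateInputError", "total_traveled_distance", "movement_summary",
    "ancova_oneway", "manova_pillai", "posthoc_contrasts",
    "partial_eta_sq_ci",
]


class DegenerateInputError(ValueError):
    """Raised for inputs on which a statistic is undefined (e.g. zero travel)."""


@dataclass
class MovementSummary:
    participant_id: str
    condition: int
    d_total: float   # ln of summed camera displacement, main phase
    d_cov: float     # same statistic, practice phase


@dataclass
class AnovaFamilyResult:
    """One F-family test: statistic, dfs, p, and partial eta squared.

    ``eta_ci`` (noncentral-F inversion, 90% by default) is computed on
    first access, since the inversion costs far more than the test.
    """

    name: str
    statistic: float            # F, or Pillai's T for MANOVA rows
    f_value: float
    df1: int
    df2: int
    p_value: float
    partial_eta_sq: float
    p_adjusted: float | None = None
    ci_level: float = 0.90
    _eta_ci: tuple | None = None

    @property
    def eta_ci(self) -> tuple[float, float]:
        if self._eta_ci is None:
            self._eta_ci = partial_eta_sq_ci(self.f_value, self.df1,
                                             self.df2, self.ci_level)
        return self._eta_ci

    def __str__(self) -> str:
        stat = (f"T = {self.statistic:.3f}, " if self.name.startswith("pillai")
                else "")
        return (f"{self.name}: {stat}F({self.df1}, {self.df2}) = "
                f"{self.f_value:.3f}, p = {self.p_value:.4f}, "
                f"partial eta^2 = {self.partial_eta_sq:.3f} "
                f"[{self.eta_ci[0]:.3f}, {self.eta_ci[1]:.3f}]")


@dataclass
class AncovaResult:
    group: AnovaFamilyResult
    covariate: AnovaFamilyResult


# ---------------------------------------------------------------------------
# traveled distance


def total_traveled_distance(session: Session, phase: str = "main",
                            log_base: float = np.e) -> tuple[float, float]:
    """Summed Euclidean camera displacement and its log score.

    Returns ``(raw, score)`` with ``score = log(raw)`` in ``log_base``.
    A session that never moves has no finite score and raises; such
    sessions are removed upstream by the short-travel exclusion.
    """
    _, cam, _ = session.phase_arrays(phase)
    if len(cam) < 2:
        raise DegenerateInputError(
            f"phase {phase!r} needs >= 2 frames for a travel distance")
    raw = float(np.linalg.norm(np.diff(cam, axis=0), axis=1).sum())
    if raw == 0.0:
        raise DegenerateInputError("zero traveled distance; log score undefined")
    return raw, float(np.log(raw) / np.log(log_base))


def movement_summary(session: Session, log_base: float = np.e) -> MovementSummary:
    """d_total (main phase) and d_cov (practice phase) for one participant."""
    _, d_total = total_traveled_distance(session, "main", log_base)
    _, d_cov = total_traveled_distance(session, "practice", log_base)
    return MovementSummary(session.participant_id, int(session.condition),
                           d_total, d_cov)


# ---------------------------------------------------------------------------
# shared helpers


def _dummies(group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, codes = np.unique(group, return_inverse=True)
    k = len(levels)
    d = np.zeros((len(group), k - 1))
    for j in range(1, k):
        d[codes == j, j - 1] = 1.0
    return d, levels

def _sse(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def partial_eta_sq_ci(f_value: float, df1: int, df2: int,
                      level: float = 0.90) -> tuple[float, float]:
    """CI for partial eta squared via noncentral-F inversion.

    The noncentrality bounds solve ``ncf.cdf(F; df1, df2, lam) = 1 -
    alpha/2`` (lower) and ``alpha/2`` (upper); they convert through
    ``eta^2 = lam / (lam + df1 + df2 + 1)``.  90% two-sided bounds are the
    conventional companion of a 5% F test.
    """
    alpha = 1.0 - level
    def _solve(target_p: float) -> float:
        # find lam with ncf.sf(f; df1, df2, lam) == target_p
        if stats.ncf.sf(f_value, df1, df2, 0.0) >= target_p:
            return 0.0
        lo, hi = 0.0, 10.0
        while stats.ncf.sf(f_value, df1, df2, hi) < target_p:
            hi *= 2.0
            if hi > 1e7:  # pragma: no cover
                return hi
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if stats.ncf.sf(f_value, df1, df2, mid) < target_p:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # sf(f; lam) increases with lam: the lower bound leaves alpha/2 of the
    # noncentral distribution above f, the upper bound 1 - alpha/2
    lam_lo = _solve(alpha / 2.0)
    lam_hi = _solve(1.0 - alpha / 2.0)
    to_eta = lambda lam: lam / (lam + df1 + df2 + 1.0)
    return (to_eta(lam_lo), to_eta(lam_hi))


# ---------------------------------------------------------------------------
# ANCOVA


def ancova_oneway(y, group, covariate) -> AncovaResult:
    """One-way ANCOVA: group dummies plus one covariate, partial SS.

    The group effect compares the full model against the model with the
    covariate only; the covariate effect against the model with group
    dummies only (Type-III-style partial sums of squares).  Error df is
    N - k - 1.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    x = np.asarray(covariate, dtype=float)
    if not (len(y) == len(group) == len(x)):
        raise ValueError("y, group, covariate must have equal length")
    d, levels = _dummies(group)
    k = len(levels)
    n = len(y)
    if k < 2:
        raise ValueError("need at least two groups")
    if n <= k + 1:
        raise ValueError("need n > k + 1 observations")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("constant covariate: design is rank deficient")

    ones = np.ones((n, 1))
    X_full = np.hstack([ones, d, x[:, None]])
    sse_full = _sse(X_full, y)
    df_err = n - k - 1
    ms_err = sse_full / df_err

    ss_group = _sse(np.hstack([ones, x[:, None]]), y) - sse_full
    f_group = (ss_group / (k - 1)) / ms_err
    p_group = float(stats.f.sf(f_group, k - 1, df_err))
    eta_g = ss_group / (ss_group + sse_full)

    ss_cov = _sse(np.hstack([ones, d]), y) - sse_full
    f_cov = ss_cov / ms_err
    p_cov = float(stats.f.sf(f_cov, 1, df_err))
    eta_c = ss_cov / (ss_cov + sse_full)

    return AncovaResult(
        group=AnovaFamilyResult("ancova_group", f_group, f_group, k - 1,
                                df_err, p_group, eta_g),
        covariate=AnovaFamilyResult("ancova_covariate", f_cov, f_cov, 1,
                                    df_err, p_cov, eta_c),
    )


# ---------------------------------------------------------------------------
# MANOVA (Pillai's trace)


def manova_pillai(Y, group) -> AnovaFamilyResult:
    """One-way MANOVA with Pillai's trace and its F approximation.

    With p responses, k groups, s = min(p, k-1), m = (|p-k+1|-1)/2 and
    n' = (N-k-p-1)/2:

        T  = sum lambda/(1+lambda)   over eigenvalues of E^-1 H
        F  = (2n'+s+1)/(2m+s+1) * (T/s) / (1 - T/s)
        df = ( s(2m+s+1), s(2n'+s+1) )

    The effect size reported is partial eta^2 = T/s.  With p = 1 this
    reduces exactly to the one-way ANOVA F.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    group = np.asarray(group)
    n, p = Y.shape
    levels = np.unique(group)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two groups")
    if n <= p + k:
        raise ValueError("need n > p + k observations")
    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for lv in levels:
        Yg = Y[group == lv]
        d = Yg.mean(axis=0) - grand
        H += len(Yg) * np.outer(d, d)
        R = Yg - Yg.mean(axis=0)
        E += R.T @ R
    try:
        EinvH = np.linalg.solve(E, H)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "error matrix E is singular; reduce the response dimension or "
            "pool collinear items") from None
    lam = np.linalg.eigvals(EinvH).real
    lam = np.clip(lam, 0.0, None)
    T = float(np.sum(lam / (1.0 + lam)))

    s = min(p, k - 1)
    m = (abs(p - k + 1) - 1) / 2.0
    nn = (n - k - p - 1) / 2.0
    df1 = int(round(s * (2 * m + s + 1)))
    df2 = int(round(s * (2 * nn + s + 1)))
    f_value = ((2 * nn + s + 1) / (2 * m + s + 1)) * (T / s) / (1.0 - T / s)
    p_value = float(stats.f.sf(f_value, df1, df2))
    eta = T / s
    return AnovaFamilyResult("pillai_manova", T, float(f_value), df1, df2,
                             p_value, eta)


def posthoc_contrasts(Y, group, pairs: Sequence[tuple], correction: str = "bonferroni",
                      covariate=None) -> list:
    """Pairwise follow-up tests with multiplicity correction.

    Each pair is re-tested on its two-group subset: Pillai MANOVA for
    multivariate ``Y`` (ANOVA when p = 1), or ANCOVA when a covariate is
    given.  Bonferroni sets ``p_adjusted = min(1, m * p)``, never below
    the raw p.
    """
    Y = np.asarray(Y, dtype=float)
    group = np.asarray(group)
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)
    results = []
    m = len(pairs)
    if m == 0:
        raise ValueError("no pairs requested")
    for pair in pairs:
        if len(pair) != 2:
            raise ValueError(f"pair must have two levels, got {pair!r}")
        mask = np.isin(group, list(pair))
        if not (np.any(group == pair[0]) and np.any(group == pair[1])):
            raise ValueError(f"pair {pair!r} not present in data")
        if covariate is not None:
            res = ancova_oneway(Y[mask].ravel(), group[mask], covariate[mask]).group
        else:
            res = manova_pillai(Y[mask], group[mask])
        res.name = f"{res.name}[{pair[0]}-{pair[1]}]"
        if correction == "bonferroni":
            res.p_adjusted = min(1.0, m * res.p_value)
        elif correction in (None, "none"):
            res.p_adjusted = res.p_value
        else:
            raise ValueError(f"unknown correction {correction!r}")
        results.append(res)
    return results


def results_table(results: Sequence[AnovaFamilyResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "test": r.name, "statistic": r.statistic, "F": r.f_value,
        "df1": r.df1, "df2": r.df2, "p": r.p_value, "p_adjusted": r.p_adjusted,
        "partial_eta_sq": r.partial_eta_sq,
        "eta_ci_low": r.eta_ci[0], "eta_ci_high": r.eta_ci[1],
    } for r in results])
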