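"""Quality filtering, fixation detection, and circular view-angles.

Three participant-level exclusion criteria mirror the study protocol: a
camera taken too far from the target at any point, an extremely short total
travel from the start, and a mean logging rate below 10 records/s.  A
participant matching *any* criterion is excluded; the report keeps both the
per-criterion counts and the overlap-adjusted union.

A *fixation* is a maximal run of frames in which the camera stays at one
location (successive displacement <= ``eps``, default exact hold — an orbit
camera only moves under user input) for at least 500 ms.  Each fixation
contributes one signed view-angle theta: the azimuth of the camera around
the artwork's vertical (y) axis, measured from the front (+z), wrapped to
(-pi, pi].  Elevation is discarded; theta is a univariate circular outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from vantage.sessions import Cohort, Session

__all__ = [
    "FixationSequence", "ExclusionConfig", "ExclusionReport",
    "UndefinedRateError", "UndefinedAngleError", "mean_record_rate",
    "apply_exclusions", "detect_fixations", "view_angle", "view_angles",
    "wrap_angle", "fixation_table",
]


class UndefinedRateError(ValueError):
    """Record rate requested on a phase with fewer than two frames."""


class UndefinedAngleError(ValueError):
    """View-angle requested for a camera with no horizontal offset."""


def wrap_angle(theta):
    """Wrap angles to the half-open interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    out = -((-theta + np.pi) % (2.0 * np.pi) - np.pi)
    return out if out.ndim else float(out)


@dataclass
class FixationSequence:
    """Dwell events of one participant: angle, dwell, mean camera position."""

    participant_id: str
    condition: int
    theta: np.ndarray          # radians in (-pi, pi], one per event
    dwell: np.ndarray          # ms
    cam: np.ndarray            # (n_events, 3) run-mean camera position

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.dwell = np.asarray(self.dwell, dtype=float)
        self.cam = np.asarray(self.cam, dtype=float).reshape(len(self.theta), 3)
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("fixation angles must be finite")

    @property
    def n_events(self) -> int:
        return len(self.theta)

    def __len__(self) -> int:
        return self.n_events


@dataclass
class ExclusionConfig:
    """Thresholds for the three exclusion criteria.

    The protocol states the criteria but not the cutoffs; the defaults
    express them relative to each participant's initial camera-target
    distance: ``d_max`` = 10x initial distance, ``min_travel`` = 1% of it.
    Absolute values can be supplied instead.
    """

    d_max: float | None = None
    d_max_ratio: float = 10.0
    min_travel: float | None = None
    min_travel_ratio: float = 0.01
    min_rate: float = 10.0     # records per second, study value
    phase: str = "main"


@dataclass
class ExclusionReport:
    counts: dict = field(default_factory=dict)       # per-criterion counts
    flagged: dict = field(default_factory=dict)      # criterion -> sorted ids
    excluded_ids: list = field(default_factory=list)  # union, sorted
    retained_ids: list = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": c, "count": self.counts[c],
                 "ids": ";".join(self.flagged[c])} for c in self.counts]
        rows.append({"criterion": "excluded_union", "count": self.n_excluded,
                     "ids": ";".join(self.excluded_ids)})
        rows.append({"criterion": "retained", "count": self.n_retained, "ids": ""})
        return pd.DataFrame(rows)


def mean_record_rate(session: Session, phase: str = "main") -> float:
    """Mean logging rate in records/s: frame count over elapsed seconds."""
    t, _, _ = session.phase_arrays(phase)
    if len(t) < 2:
        raise UndefinedRateError(
            f"phase {phase!r} of {session.participant_id!r} has "
            f"{len(t)} frame(s); rate undefined"
        )
    elapsed_s = (t[-1] - t[0]) / 1000.0
    if elapsed_s <= 0:
        raise UndefinedRateError("phase spans zero time")
    return len(t) / elapsed_s


def apply_exclusions(cohort: Cohort, cfg: ExclusionConfig | None = None
                     ) -> tuple[Cohort, ExclusionReport]:
    """Apply the three participant-level criteria; return retained cohort.

    A session failing *any* criterion is excluded; the union is
    overlap-adjusted, so per-criterion counts may sum to more than the
    number excluded.
    """
    cfg = cfg or ExclusionConfig()
    flagged = {"too_far": [], "too_short_travel": [], "low_rate": []}
    for s in cohort.sessions:
        t, cam, tgt = s.phase_arrays(cfg.phase)
        if len(t) < 2:
            flagged["low_rate"].append(s.participant_id)
            continue
        d0 = float(np.linalg.norm(cam[0] - tgt[0]))
        d_max = cfg.d_max if cfg.d_max is not None else cfg.d_max_ratio * d0
        min_travel = (cfg.min_travel if cfg.min_travel is not None
                      else cfg.min_travel_ratio * d0)
        dist = np.linalg.norm(cam - tgt, axis=1)
        if dist.max() > d_max:
            flagged["too_far"].append(s.participant_id)
        travel = float(np.linalg.norm(np.diff(cam, axis=0), axis=1).sum())
        if travel < min_travel:
            flagged["too_short_travel"].append(s.participant_id)
        if mean_record_rate(s, cfg.phase) < cfg.min_rate:
            flagged["low_rate"].append(s.participant_id)

    union = sorted(set().union(*flagged.values()))
    retained = [pid for pid in cohort.participant_ids if pid not in set(union)]
    report = ExclusionReport(
        counts={k: len(v) for k, v in flagged.items()},
        flagged={k: sorted(v) for k, v in flagged.items()},
        excluded_ids=union,
        retained_ids=retained,
    )
    return cohort.subset(retained), report


def detect_fixations(session: Session, min_dwell_ms: float = 500.0,
                     eps: float = 0.0, phase: str = "main") -> FixationSequence:
    """Extract stationary dwell events of at least ``min_dwell_ms``.

    A run is a maximal block of consecutive frames whose successive camera
    displacements are all <= ``eps``; its duration is last minus first
    frame time.  Each qualifying run yields one event located at the run's
    mean camera position, with theta computed against the run's mean
    target.
    """
    t, cam, tgt = session.phase_arrays(phase)
    if len(t) == 0:
        return FixationSequence(session.participant_id, int(session.condition),
                                np.empty(0), np.empty(0), np.empty((0, 3)))
    # run boundaries: displacement > eps starts a new run
    if len(t) == 1:
        run_id = np.zeros(1, dtype=int)
    else:
        step = np.linalg.norm(np.diff(cam, axis=0), axis=1)
        run_id = np.concatenate([[0], np.cumsum(step > eps)])
    thetas, dwells, cams = [], [], []
    for rid in np.unique(run_id):
        m = run_id == rid
        dur = float(t[m][-1] - t[m][0])
        if dur < min_dwell_ms:
            continue
        c_mean = cam[m].mean(axis=0)
        g_mean = tgt[m].mean(axis=0)
        thetas.append(view_angle(c_mean, g_mean))
        dwells.append(dur)
        cams.append(c_mean)
    return FixationSequence(
        session.participant_id, int(session.condition),
        np.asarray(thetas), np.asarray(dwells),
        np.asarray(cams).reshape(len(thetas), 3),
    )


def view_angle(cam, tgt) -> float:
    """Signed azimuth of the camera about the target's vertical axis.

    Projected to the ground (xz) plane and measured from the front (+z):
    0 means directly in front, +pi/2 to the stimulus' x side, and +-pi
    directly behind.  Elevation (y) is ignored.
    """
    d = np.asarray(cam, dtype=float) - np.asarray(tgt, dtype=float)
    dx, dz = d[..., 0], d[..., 2]
    if np.ndim(dx) == 0 and dx == 0.0 and dz == 0.0:
        raise UndefinedAngleError("camera has no horizontal offset from target")
    theta = np.arctan2(dx, dz)
    return wrap_angle(theta)


def view_angles(cam: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    """Vectorized :func:`view_angle` over (n, 3) arrays."""
    d = np.asarray(cam, dtype=float) - np.asarray(tgt, dtype=float)
    degenerate = (d[:, 0] == 0.0) & (d[:, 2] == 0.0)
    if degenerate.any():
        raise UndefinedAngleError(
            f"{int(degenerate.sum())} frame(s) with camera vertically above target"
        )
    return wrap_angle(np.arctan2(d[:, 0], d[:, 2]))


def fixation_table(sequences: Iterable[FixationSequence]) -> pd.DataFrame:
    """Long-format table of fixation events for CSV export."""
    rows = []
    for seq in sequences:
        for j in range(seq.n_events):
            rows.append({
                "participant_id": seq.participant_id,
                "condition": seq.condition,
                "event": j,
                "theta_rad": seq.theta[j],
                "dwell_ms": seq.dwell[j],
                "cam_x": seq.cam[j, 0], "cam_y": seq.cam[j, 1], "cam_z": seq.cam[j, 2],
            })
    return pd.DataFrame(rows, columns=[
        "participant_id", "condition", "event", "theta_rad", "dwell_ms",
        "cam_x", "cam_y", "cam_z"])
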