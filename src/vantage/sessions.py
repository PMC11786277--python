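"""Data model and file I/O for trajectory logs and cohort manifests.

A *session* is one participant's interaction with the virtual exhibition:
a stream of timestamped camera and look-at-target coordinates, logged by the
browser at up to 60 records/s and saved as TSV.  A *cohort* bundles the
sessions of all participants with their condition assignment and the
nine-dimension Likert responses collected after viewing.

Coordinates are right-handed, y-up, dimensionless scene units; the stimulus
faces +z and the camera starts in front of it (on the +z side of the
target).  Timestamps are integer milliseconds at browser-frame granularity;
duplicated timestamps collapse to the last logged row.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES", "TSV_COLUMNS", "LIKERT_DIMENSIONS",
    "Condition", "TrajectoryFrame", "Session", "Cohort",
    "TrajectoryFormatError", "CohortError",
    "read_trajectory_tsv", "write_trajectory_tsv",
    "read_cohort_manifest", "write_cohort_manifest", "write_table",
]

PHASES = ("practice", "main")

#: Fixed trajectory-log schema (the recording system names TSV but not its
#: columns; this layout is this package's convention).
TSV_COLUMNS = ("t_ms", "cam_x", "cam_y", "cam_z", "tgt_x", "tgt_y", "tgt_z", "phase")

#: The nine Likert dimensions, in questionnaire order.
LIKERT_DIMENSIONS = (
    "liking", "admiration", "empathy", "imagination", "inspiration",
    "beauty", "boredom", "interest", "nostalgia",
)

#: Duration of a complete main viewing trial, milliseconds.
MAIN_TRIAL_MS = 100_000


class TrajectoryFormatError(ValueError):
    """Raised when a trajectory log cannot be parsed against the schema."""


class CohortError(ValueError):
    """Raised for malformed cohort manifests (bad labels, duplicate ids)."""


class Condition(enum.IntEnum):
    """Instruction condition; integer codes match the model's c_i coding."""

    NARRATIVE = 0
    PROCESS = 1
    CREATOR = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label) -> "Condition":
        if isinstance(label, Condition):
            return label
        if isinstance(label, (int, np.integer)):
            return cls(int(label))
        key = str(label).strip().lower()
        try:
            return cls[key.upper()]
        except KeyError:
            raise CohortError(f"unknown condition label: {label!r}") from None


@dataclass(frozen=True)
class TrajectoryFrame:
    """One logged record: time (ms), camera and target position, phase."""

    t: int
    cam: np.ndarray
    tgt: np.ndarray
    phase: str

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("frame time must be non-negative")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        for v in (self.cam, self.tgt):
            if not np.all(np.isfinite(v)):
                raise ValueError("coordinates must be finite")


class Session:
    """Ordered trajectory of one participant, stored as column arrays.

    Frames are kept as NumPy arrays (``t`` int64 ms, ``cam``/``tgt``
    float (n, 3), ``phase`` str array) rather than per-frame objects, so
    whole-cohort computations stay vectorized.
    """

    def __init__(self, participant_id: str, condition, t, cam, tgt, phase):
        self.participant_id = str(participant_id)
        self.condition = Condition.from_label(condition)
        t = np.asarray(t, dtype=np.int64)
        cam = np.asarray(cam, dtype=float).reshape(len(t), 3)
        tgt = np.asarray(tgt, dtype=float).reshape(len(t), 3)
        phase = np.asarray(phase, dtype="U8")
        if not (len(t) == len(cam) == len(tgt) == len(phase)):
            raise ValueError("frame columns must have equal length")
        if len(t) and t.min() < 0:
            raise ValueError("frame times must be non-negative")
        if not (np.isfinite(cam).all() and np.isfinite(tgt).all()):
            raise ValueError("coordinates must be finite")
        bad = set(np.unique(phase)) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        # canonical order: phase blocks (practice first), time-sorted inside,
        # duplicate timestamps collapsed to the last occurrence
        order = np.lexsort((np.arange(len(t)), t, _phase_rank(phase)))
        t, cam, tgt, phase = t[order], cam[order], tgt[order], phase[order]
        keep = np.ones(len(t), dtype=bool)
        if len(t) > 1:
            same = (t[1:] == t[:-1]) & (phase[1:] == phase[:-1])
            keep[:-1][same] = False
        self.t, self.cam, self.tgt, self.phase = t[keep], cam[keep], tgt[keep], phase[keep]

    # -- accessors ---------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def phase_mask(self, phase: str) -> np.ndarray:
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        return self.phase == phase

    def phase_arrays(self, phase: str):
        """Return ``(t, cam, tgt)`` restricted to one phase."""
        m = self.phase_mask(phase)
        return self.t[m], self.cam[m], self.tgt[m]

    def frames(self) -> Iterator[TrajectoryFrame]:
        for i in range(self.n_frames):
            yield TrajectoryFrame(int(self.t[i]), self.cam[i], self.tgt[i], str(self.phase[i]))

    def __len__(self) -> int:
        return self.n_frames

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Session)
            and self.participant_id == other.participant_id
            and self.condition == other.condition
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.cam, other.cam)
            and np.array_equal(self.tgt, other.tgt)
            and np.array_equal(self.phase, other.phase)
        )

    def __repr__(self) -> str:
        return (f"Session({self.participant_id!r}, {self.condition.label}, "
                f"{self.n_frames} frames)")


def _phase_rank(phase: np.ndarray) -> np.ndarray:
    rank = np.zeros(len(phase), dtype=np.int8)
    rank[phase == "main"] = 1
    return rank


@dataclass
class Cohort:
    """All sessions of a study plus the per-participant Likert responses.

    ``likert`` is a DataFrame indexed by participant id with the nine
    dimension columns of :data:`LIKERT_DIMENSIONS`; it may be empty when
    only trajectories are analysed.
    """

    sessions: list[Session] = field(default_factory=list)
    likert: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(LIKERT_DIMENSIONS))
    )

    def __post_init__(self):
        ids = [s.participant_id for s in self.sessions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate participant ids: {dupes}")
        unknown = set(self.likert.index) - set(ids)
        if unknown:
            raise CohortError(
                f"likert rows without a session: {sorted(unknown)[:5]}"
            )

    @property
    def participant_ids(self) -> list[str]:
        return [s.participant_id for s in self.sessions]

    def group_sizes(self) -> dict[str, int]:
        sizes = {c.label: 0 for c in Condition}
        for s in self.sessions:
            sizes[s.condition.label] += 1
        return sizes

    def session(self, participant_id: str) -> Session:
        for s in self.sessions:
            if s.participant_id == participant_id:
                return s
        raise KeyError(participant_id)

    def subset(self, ids: Iterable[str]) -> "Cohort":
        keep = set(ids)
        sessions = [s for s in self.sessions if s.participant_id in keep]
        likert = self.likert.loc[self.likert.index.isin(keep)]
        return Cohort(sessions=sessions, likert=likert)

    def __len__(self) -> int:
        return len(self.sessions)


# ---------------------------------------------------------------------------
# trajectory TSV I/O


def read_trajectory_tsv(source, participant_id="", condition=Condition.NARRATIVE,
                        schema=None, max_bad_fraction=0.01) -> Session:
    """Parse one participant's TSV trajectory log into a :class:`Session`.

    Parameters
    ----------
    source
        Path, file object, or byte/str stream of tab-separated text with a
        header row.
    schema
        Optional mapping from the canonical column names in
        :data:`TSV_COLUMNS` to the names used in the file.
    max_bad_fraction
        Parsing fails if more than this fraction of data rows is
        unparseable or non-finite (row-level problems below the threshold
        are dropped and counted on ``session.n_rejected_rows``).
    """
    schema = dict(schema or {})
    colmap = {c: schema.get(c, c) for c in TSV_COLUMNS}
    try:
        raw = pd.read_csv(source, sep="\t", dtype=str, skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TrajectoryFormatError(f"could not read TSV: {exc}") from exc
    raw.columns = [str(c).strip() for c in raw.columns]
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise TrajectoryFormatError(f"missing required columns: {missing}")

    n_rows = len(raw)
    num_cols = [colmap[c] for c in TSV_COLUMNS[:-1]]
    num = raw[num_cols].apply(pd.to_numeric, errors="coerce")
    phase = raw[colmap["phase"]].astype(str).str.strip().str.lower()
    ok = num.notna().all(axis=1) & np.isfinite(num.to_numpy(dtype=float)).all(axis=1)
    ok &= phase.isin(PHASES)
    ok &= num[colmap["t_ms"]] >= 0
    n_bad = int(n_rows - ok.sum())
    if n_rows and n_bad > max_bad_fraction * n_rows:
        raise TrajectoryFormatError(
            f"{n_bad}/{n_rows} rows unparseable (> {max_bad_fraction:.0%} allowed)"
        )
    # reconvert the retained rows from text with the correctly-rounded
    # parser, so written coordinates round-trip bit-identically
    kept = raw.loc[ok]
    as_float = lambda cols: kept[[colmap[c] for c in cols]].to_numpy(str).astype(float)
    session = Session(
        participant_id=participant_id,
        condition=condition,
        t=as_float(["t_ms"]).ravel().astype(np.int64),
        cam=as_float(["cam_x", "cam_y", "cam_z"]),
        tgt=as_float(["tgt_x", "tgt_y", "tgt_z"]),
        phase=phase[ok].to_numpy(),
    )
    session.n_rejected_rows = n_bad
    return session


def write_trajectory_tsv(session: Session, path) -> None:
    """Write a session back to the canonical TSV layout."""
    df = pd.DataFrame({
        "t_ms": session.t,
        "cam_x": session.cam[:, 0], "cam_y": session.cam[:, 1], "cam_z": session.cam[:, 2],
        "tgt_x": session.tgt[:, 0], "tgt_y": session.tgt[:, 1], "tgt_z": session.tgt[:, 2],
        "phase": session.phase,
    })
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort manifest I/O


def read_cohort_manifest(source, sessions: Sequence[Session] | None = None) -> Cohort:
    """Read a cohort manifest CSV (id, condition, nine Likert columns).

    When ``sessions`` is given they are attached by participant id;
    otherwise frameless placeholder sessions are created so the manifest
    can be validated stand-alone.
    """
    df = pd.read_csv(source, dtype={"id": str})
    if df.empty and len(df.columns) <= 1:
        warnings.warn("empty cohort manifest", stacklevel=2)
        return Cohort()
    required = ["id", "condition", *LIKERT_DIMENSIONS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"manifest missing columns: {missing}")
    if df.empty:
        warnings.warn("empty cohort manifest", stacklevel=2)
        return Cohort()
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise CohortError(f"duplicate participant ids in manifest: {dupes}")
    conditions = {}
    for _, row in df.iterrows():
        try:
            conditions[row["id"]] = Condition.from_label(row["condition"])
        except CohortError:
            raise CohortError(
                f"unknown condition label {row['condition']!r} for id {row['id']!r}"
            ) from None

    by_id = {s.participant_id: s for s in (sessions or [])}
    out_sessions = []
    for pid, cond in conditions.items():
        if pid in by_id:
            s = by_id[pid]
            if s.condition != cond:
                raise CohortError(f"condition mismatch for id {pid!r}")
            out_sessions.append(s)
        else:
            out_sessions.append(Session(pid, cond, [], np.empty((0, 3)),
                                        np.empty((0, 3)), []))
    likert = df.set_index("id")[list(LIKERT_DIMENSIONS)].astype(float)
    return Cohort(sessions=out_sessions, likert=likert)


def write_cohort_manifest(cohort: Cohort, path) -> None:
    rows = []
    for s in cohort.sessions:
        row = {"id": s.participant_id, "condition": s.condition.label}
        if s.participant_id in cohort.likert.index:
            row.update(cohort.likert.loc[s.participant_id].to_dict())
        rows.append(row)
    pd.DataFrame(rows, columns=["id", "condition", *LIKERT_DIMENSIONS]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# generic tables


def write_table(records, path, format: str = "csv") -> Path:
    """Write homogeneous records (DataFrame, dataclasses, dicts) to disk.

    Numeric fields round-trip exactly: pandas writes shortest-repr floats,
    which re-parse to the identical float64. An empty record list yields a
    header-only file when the column set is known.
    """
    if format not in ("csv", "tsv"):
        raise ValueError(f"unsupported format {format!r}")
    sep = "," if format == "csv" else "\t"
    df = _as_dataframe(records)
    path = Path(path)
    try:
        df.to_csv(path, sep=sep, index=False)
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc
    return path


def _as_dataframe(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    records = list(records)
    if not records:
        return pd.DataFrame()
    first = records[0]
    if hasattr(first, "__dataclass_fields__"):
        cols = list(first.__dataclass_fields__)
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
    if hasattr(first, "_fields"):  # namedtuple
        return pd.DataFrame(records, columns=list(first._fields))
    return pd.DataFrame(records)


def read_table(path, format: str = "csv") -> pd.DataFrame:
    sep = "," if format == "csv" else "\t"
    return pd.read_csv(path, sep=sep, float_precision="round_trip")
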