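"""Ray-cast dwell-surface mapping over the stimulus mesh.

Viewing time is projected onto the artwork by casting, for every frame (or
fixation), the line from the camera through the current look-at target —
the orbit camera always faces its target, so this line is the natural gaze
proxy when no eye tracker is available; the resulting surface estimate is
approximate by construction.  Hit points accumulate the frame's dwell into
a voxel grid over the mesh bounding box, separately per instruction
condition.  Normalising each condition over the occupied voxels gives the
proportions (p_n, p_p, p_c), whose ratio drives the condition coloring:
green where narrative-condition gaze dominates, red for process, blue for
creator; voxels with near-equal proportions blend toward white and are
dropped beyond a whiteness threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from vantage.preprocess import FixationSequence
from vantage.sessions import Condition, Session

__all__ = [
    "DwellMap", "load_mesh", "ray_mesh_first_hit", "accumulate_dwell",
    "condition_color", "dwell_map_table",
]

_COND_KEYS = ("narrative", "process", "creator")


def load_mesh(source) -> trimesh.Trimesh:
    """Load a triangle mesh (OBJ or anything trimesh reads)."""
    mesh = trimesh.load(source, force="mesh")
    if len(mesh.faces) == 0:
        raise ValueError("mesh has no faces")
    return mesh


def _first_hits(origins: np.ndarray, directions: np.ndarray,
                mesh: trimesh.Trimesh, chunk: int = 256):
    """Nearest forward hit of each ray, by vectorised Moller-Trumbore.

    Directions need not be normalised; the returned distance is along the
    unit direction.  Ties at identical distance resolve to the lowest
    face index (argmin keeps the first minimum).  All faces are tested
    per ray — no broad phase — which is ample for stimulus-scale meshes.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(directions, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("ray direction must be nonzero")
    d_unit = directions / norms[:, None]
    tri = mesh.triangles                          # (F, 3, 3)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    eps = 1e-12
    n_rays = len(origins)
    best_t = np.full(n_rays, np.inf)
    best_f = np.full(n_rays, -1, dtype=int)
    for lo in range(0, n_rays, chunk):
        o = origins[lo:lo + chunk][:, None, :]    # (r, 1, 3)
        d = d_unit[lo:lo + chunk][:, None, :]
        p = np.cross(d, e2[None, :, :])           # (r, F, 3)
        det = np.einsum("fk,rfk->rf", e1, p)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(np.abs(det) > eps, 1.0 / det, 0.0)
            s = o - v0[None, :, :]
            u = np.einsum("rfk,rfk->rf", s, p) * inv
            q = np.cross(s, e1[None, :, :])
            v = np.einsum("rfk,rfk->rf", d, q) * inv
            t = np.einsum("fk,rfk->rf", e2, q) * inv
        valid = ((np.abs(det) > eps) & (u >= -1e-9) & (v >= -1e-9)
                 & (u + v <= 1.0 + 1e-9) & (t > 1e-9))
        t = np.where(valid, t, np.inf)
        idx = np.argmin(t, axis=1)
        tmin = t[np.arange(len(idx)), idx]
        hit = np.isfinite(tmin)
        best_t[lo:lo + chunk] = np.where(hit, tmin, np.inf)
        best_f[lo:lo + chunk] = np.where(hit, idx, -1)
    hit = best_f >= 0
    points = np.full_like(origins, np.nan)
    points[hit] = origins[hit] + best_t[hit, None] * d_unit[hit]
    return hit, points, best_f, best_t


def ray_mesh_first_hit(origin, direction, mesh: trimesh.Trimesh):
    """Nearest forward intersection of one ray with the mesh.

    Returns ``(point, face_index, distance)`` or ``None`` on a miss.
    Ties at identical distance resolve to the lowest face index.
    """
    hit, points, faces, t = _first_hits(np.asarray(origin, dtype=float)[None],
                                        np.asarray(direction, dtype=float)[None],
                                        mesh)
    if not hit[0]:
        return None
    return points[0], int(faces[0]), float(t[0])


@dataclass
class DwellMap:
    """Voxelised per-condition dwell over the mesh bounding box."""

    origin: np.ndarray                 # grid corner
    edge: float                        # voxel edge length h
    shape: tuple                       # (nx, ny, nz)
    dwell: dict = field(default_factory=dict)   # condition label -> 3D array, ms

    def proportions(self) -> dict:
        """Per-condition dwell proportions over occupied voxels (sum to 1)."""
        out = {}
        for key, arr in self.dwell.items():
            total = arr.sum()
            out[key] = arr / total if total > 0 else arr
        return out

    def occupied(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for arr in self.dwell.values():
            m |= arr > 0
        return m

    def voxel_index(self, points) -> np.ndarray:
        idx = np.floor((np.asarray(points, dtype=float) - self.origin)
                       / self.edge).astype(int)
        return np.clip(idx, 0, np.asarray(self.shape) - 1)

    def voxel_center(self, idx) -> np.ndarray:
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.edge


def accumulate_dwell(sessions, mesh: trimesh.Trimesh, h: float | None = None,
                     use: str = "frames", phase: str = "main") -> DwellMap:
    """Cast camera->target rays and accumulate viewing time per voxel.

    ``sessions`` is an iterable of :class:`Session` (``use='frames'``:
    each frame contributes the interval to the next frame) or of
    :class:`FixationSequence` (``use='fixations'``: each event contributes
    its dwell, cast from the event's mean camera position toward the mesh
    centroid).  ``h`` defaults to 1/32 of the largest bounding-box extent.
    """
    if use not in ("frames", "fixations"):
        raise ValueError("use must be 'frames' or 'fixations'")
    extents = mesh.bounds[1] - mesh.bounds[0]
    edge = h if h is not None else float(extents.max()) / 32.0
    # pad half a voxel so boundary hits never clip out of the grid
    origin = mesh.bounds[0] - 0.5 * edge
    shape = tuple(int(np.ceil(e / edge)) + 1 for e in extents + edge)
    dmap = DwellMap(origin=origin, edge=edge, shape=shape,
                    dwell={k: np.zeros(shape) for k in _COND_KEYS})

    n_hits = 0
    for item in sessions:
        if use == "frames":
            if not isinstance(item, Session):
                raise TypeError("use='frames' expects Session objects")
            t, cam, tgt = item.phase_arrays(phase)
            if len(t) < 2:
                continue
            weights = np.diff(t).astype(float)  # ms until the next frame
            origins, dirs = cam[:-1], tgt[:-1] - cam[:-1]
            label = Condition(item.condition).label
        else:
            if not isinstance(item, FixationSequence):
                raise TypeError("use='fixations' expects FixationSequence objects")
            if item.n_events == 0:
                continue
            weights = item.dwell.astype(float)
            origins = item.cam
            dirs = mesh.bounds.mean(axis=0)[None, :] - item.cam
            label = Condition(item.condition).label
        ok = np.linalg.norm(dirs, axis=1) > 0
        origins, dirs, weights = origins[ok], dirs[ok], weights[ok]
        if len(origins) == 0:
            continue
        hit, locations, _, _ = _first_hits(origins, dirs, mesh)
        if not hit.any():
            continue
        vox = dmap.voxel_index(locations[hit])
        np.add.at(dmap.dwell[label],
                  (vox[:, 0], vox[:, 1], vox[:, 2]), weights[hit])
        n_hits += int(hit.sum())
    if n_hits == 0:
        warnings.warn("no camera->target ray hit the mesh; dwell map is empty",
                      stacklevel=2)
    return dmap


def condition_color(p_n: float, p_p: float, p_c: float,
                    whiteness_threshold: float = 0.15):
    """Color of one voxel from its per-condition dwell proportions.

    Channels are the proportions normalised by their maximum and mapped to
    (narrative -> green, process -> red, creator -> blue); equal
    proportions give white.  Returns ``(r, g, b)`` or ``None`` when the
    voxel is closer to white than the threshold (minimum channel above
    ``1 - whiteness_threshold``).
    """
    p = np.array([p_n, p_p, p_c], dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    m = p.max()
    if m == 0.0:
        raise ValueError("all-zero proportions have no color")
    g, r, b = p / m
    if min(r, g, b) > 1.0 - whiteness_threshold:
        return None
    return (float(r), float(g), float(b))


def dwell_map_table(dmap: DwellMap, whiteness_threshold: float = 0.15
                    ) -> pd.DataFrame:
    """Flat export: voxel index, center, per-condition dwell, color.

    Voxels dropped by the whiteness rule carry empty color columns.
    """
    props = dmap.proportions()
    occ = np.argwhere(dmap.occupied())
    rows = []
    for idx in occ:
        i, j, k = (int(v) for v in idx)
        center = dmap.voxel_center(idx)
        p = {key: float(props[key][i, j, k]) for key in _COND_KEYS}
        if sum(p.values()) > 0:
            color = condition_color(p["narrative"], p["process"], p["creator"],
                                    whiteness_threshold)
        else:  # pragma: no cover - occupied implies some dwell
            color = None
        rows.append({
            "ix": i, "iy": j, "iz": k,
            "x": center[0], "y": center[1], "z": center[2],
            "dwell_n": float(dmap.dwell["narrative"][i, j, k]),
            "dwell_p": float(dmap.dwell["process"][i, j, k]),
            "dwell_c": float(dmap.dwell["creator"][i, j, k]),
            "p_n": p["narrative"], "p_p": p["process"], "p_c": p["creator"],
            "r": color[0] if color else np.nan,
            "g": color[1] if color else np.nan,
            "b": color[2] if color else np.nan,
            "dropped_white": color is None,
        })
    return pd.DataFrame(rows)
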