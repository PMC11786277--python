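import io

import numpy as np
import pytest

from vantage.sessions import Session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_session(t, cam, tgt=None, phase="main", participant_id="p0",
                 condition=0):
    """Build a Session from loose arrays, defaulting target to the origin."""
    t = np.asarray(t)
    cam = np.asarray(cam, dtype=float).reshape(len(t), 3)
    if tgt is None:
        tgt = np.zeros_like(cam)
    if isinstance(phase, str):
        phase = np.full(len(t), phase)
    return Session(participant_id, condition, t, cam, tgt, phase)


def session_tsv(rows, header="t_ms\tcam_x\tcam_y\tcam_z\ttgt_x\ttgt_y\ttgt_z\tphase"):
    return io.StringIO("\n".join([header, *rows]) + "\n")


@pytest.fixture
def random_session(rng):
    """A 200-frame main-phase session with a short practice block."""
    def _make(n=200, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        t_p = np.arange(0, 50, 5, dtype=np.int64) * 100
        t_m = np.sort(r.choice(np.arange(0, 100_000), size=n, replace=False))
        cam = np.cumsum(r.normal(0, 0.1, (n + len(t_p), 3)), axis=0) + [0, 1, 5]
        tgt = np.tile([0.0, 1.0, 0.0], (n + len(t_p), 1))
        phase = np.array(["practice"] * len(t_p) + ["main"] * n)
        return Session("rnd", 1, np.concatenate([t_p, t_m]), cam, tgt, phase)
    return _make
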