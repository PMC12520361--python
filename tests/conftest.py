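"""Shared fixtures: ground-truth parameters, limit cycle, snapshot tables.

Session scope keeps the expensive artefacts (limit cycle integration,
5000-cell snapshots) shared across test modules.
"""

import numpy as np
import pytest

from cycletime.model import ModelParameters
from cycletime.synthetic import (
    SnapshotSpec,
    make_limit_cycle,
    sample_arrested_snapshot,
    sample_snapshot,
)


def rk4_reference(rhs_fn, s0, t_end, dt):
    """Plain-Python fixed-step RK4: independent oracle for integrators."""
    n = int(round(t_end / dt))
    s = np.asarray(s0, dtype=float).copy()
    out = np.empty((n + 1, s.size))
    out[0] = s
    for i in range(n):
        k1 = rhs_fn(s)
        k2 = rhs_fn(s + 0.5 * dt * k1)
        k3 = rhs_fn(s + 0.5 * dt * k2)
        k4 = rhs_fn(s + dt * k3)
        s = s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = s
    return np.linspace(0.0, n * dt, n + 1), out


@pytest.fixture(scope="session")
def truth():
    return ModelParameters()


@pytest.fixture(scope="session")
def limit_cycle(truth):
    return make_limit_cycle(truth, use_fast=True)


@pytest.fixture(scope="session")
def snapshot_5000(limit_cycle):
    spec = SnapshotSpec(n_cells=5000, noise_cv=0.2, seed=11)
    return sample_snapshot(limit_cycle, spec)


@pytest.fixture(scope="session")
def arrested_tables(truth, limit_cycle):
    out = {}
    for cond, seed in (("nocodazole", 21), ("palbociclib", 22)):
        spec = SnapshotSpec(n_cells=600, noise_cv=0.2, condition=cond, seed=seed)
        out[cond] = sample_arrested_snapshot(truth, limit_cycle, spec)
    return out


@pytest.fixture(scope="session")
def embedded(snapshot_5000, limit_cycle):
    """Full untreated embedding bundle used by several modules."""
    import numpy as np

    from cycletime import pseudotime as pt

    tab = snapshot_5000
    mm = pt.preprocess(tab)
    coords = pt.cmd_embed(mm)
    circle = pt.fit_circle(coords)
    emb = pt.angles(coords, circle, mm)
    boundaries = pt.phase_boundaries(emb)
    zero = pt.mg1_angle(emb, mm, boundaries if len(boundaries) else None)
    emb = emb.with_zero(zero)
    asn = pt.ergodic_times(emb, limit_cycle.period)
    return {"tab": tab, "mm": mm, "coords": coords, "circle": circle,
            "emb": emb, "asn": asn, "T": limit_cycle.period}
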