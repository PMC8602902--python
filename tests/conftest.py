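"""Shared fixtures: synthetic samples, strategies and a random-strategy
generator used by the oracle-equivalence and serialization tests."""

from __future__ import annotations

import numpy as np
import pytest

from cytogate import transforms as tr
from cytogate.compensation import SpilloverMatrix
from cytogate.gates import (
    BooleanGate,
    Dimension,
    Divider,
    EllipsoidGate,
    PolygonGate,
    RectangleGate,
    full_quadrant_grid,
)
from cytogate.strategy import ROOT, GatingStrategy
from cytogate.synth import three_population_sample

CHANNELS = ["FSC-A", "SSC-A", "FL1-A", "FL2-A"]


@pytest.fixture(scope="session")
def tri_pop():
    """10k-event 3-population mixture (60/30/10%) with truth labels."""
    return three_population_sample(10000, seed=7)


@pytest.fixture()
def small_sample():
    sample, _ = three_population_sample(1000, seed=11, sample_id="small")
    return sample


def base_strategy() -> GatingStrategy:
    st = GatingStrategy()
    st.add_transform(tr.logicle(262144, 0.5, 4.5, 0, id="lgl"))
    st.add_transform(tr.linear(262144, 0, id="lin"))
    st.add_comp_matrix(SpilloverMatrix(
        ["FL1-A", "FL2-A"], np.array([[1.0, 0.08], [0.04, 1.0]]), id="cm"))
    return st


def random_strategy(rng: np.random.Generator, n_gates: int = 5) -> GatingStrategy:
    """A random strategy mixing all five gate kinds over CHANNELS.

    Boolean gates only reference already-added paths; polygon/rectangle
    coordinates live in the referenced dimension's space (transformed
    [0, 1]-ish or raw instrument scale).
    """
    st = base_strategy()
    paths = [ROOT]

    def rand_dim(bounded=False):
        ch = CHANNELS[rng.integers(len(CHANNELS))]
        comp = "cm" if (ch.startswith("FL") and rng.random() < 0.5) else "none"
        xf = "lgl" if (ch.startswith("FL") and rng.random() < 0.7) else None
        lo, hi = (0.0, 1.0) if xf else (0.0, 150000.0)
        mn = mx = None
        if bounded:
            a, b = np.sort(rng.uniform(lo, hi, 2))
            mn = float(a) if rng.random() < 0.8 else None
            mx = float(b) if (rng.random() < 0.8 or mn is None) else None
        return Dimension(ch, comp, xf, mn, mx), (lo, hi)

    kinds = ["rect", "poly", "ellipse", "quad", "bool"]
    for gi in range(n_gates):
        kind = kinds[gi % len(kinds)] if gi < len(kinds) else \
            kinds[rng.integers(len(kinds))]
        parent = paths[rng.integers(len(paths))]
        name = f"G{gi}"
        if kind == "rect":
            ndim = int(rng.integers(1, 3))
            gate = RectangleGate(name, [rand_dim(bounded=True)[0]
                                        for _ in range(ndim)])
        elif kind == "poly":
            (d1, (lo1, hi1)) = rand_dim()
            (d2, (lo2, hi2)) = rand_dim()
            k = int(rng.integers(3, 7))
            verts = np.column_stack([rng.uniform(lo1, hi1, k),
                                     rng.uniform(lo2, hi2, k)])
            gate = PolygonGate(name, [d1, d2], verts)
        elif kind == "ellipse":
            (d1, (lo1, hi1)) = rand_dim()
            (d2, (lo2, hi2)) = rand_dim()
            mean = [rng.uniform(lo1, hi1), rng.uniform(lo2, hi2)]
            a = rng.uniform(0.05, 0.5, (2, 2))
            cov = a @ a.T + np.diag([1e-3, 1e-3])
            scale = np.diag([(hi1 - lo1), (hi2 - lo2)])
            cov = scale @ cov @ scale
            gate = EllipsoidGate(name, [d1, d2], mean, cov,
                                 float(rng.uniform(0.5, 3.0)))
        elif kind == "quad":
            dividers = []
            for di in range(int(rng.integers(1, 3))):
                dim, (lo, hi) = rand_dim()
                n_split = int(rng.integers(1, 3))
                splits = tuple(np.sort(rng.uniform(lo, hi, n_split)))
                dividers.append(Divider(f"{name}d{di}", dim, splits))
            gate = full_quadrant_grid(name, dividers)
        else:
            n_ops = 1 if rng.random() < 0.3 else int(rng.integers(2, 4))
            candidates = [p for p in paths if p != ROOT] or [ROOT]
            ops = [(candidates[rng.integers(len(candidates))],
                    bool(rng.random() < 0.4)) for _ in range(n_ops)]
            op = "NOT" if n_ops == 1 and rng.random() < 0.5 else \
                ("AND" if rng.random() < 0.5 else "OR")
            if op == "NOT":
                ops = ops[:1]
            gate = BooleanGate(name, op, ops)
        path = st.add_gate(gate, parent)
        paths.append(path)
        if hasattr(gate, "quadrants"):
            paths.extend(path + (q.id,) for q in gate.quadrants)
    return st
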