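"""Independent scalar re-implementations used as test oracles.

Everything here is deliberately slow, per-event, pure Python, and written
without reference to the vectorized implementations it checks.
"""

from __future__ import annotations

import numpy as np

from cytogate.gates import (
    BooleanGate,
    EllipsoidGate,
    PolygonGate,
    QuadrantGate,
    RectangleGate,
)
from cytogate.strategy import ROOT, _EvalContext, _QuadrantCell


def point_in_rectangle(point, gate) -> bool:
    for v, dim in zip(point, gate.dimensions):
        if dim.range_min is not None and v < dim.range_min:
            return False
        if dim.range_max is not None and v > dim.range_max:
            return False
    return True


def point_in_polygon(x, y, verts, tol) -> bool:
    """Even-odd winding with explicit on-segment boundary check."""
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if (abs(cross) <= tol
                and min(x1, x2) - tol <= x <= max(x1, x2) + tol
                and min(y1, y2) - tol <= y <= max(y1, y2) + tol):
            return True
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


def point_in_ellipsoid(point, gate) -> bool:
    diff = np.asarray(point, dtype=float) - gate.mean
    d2 = float(diff @ np.linalg.inv(gate.covariance) @ diff)
    return d2 <= gate.distance_square


def quadrant_cell_of(point, gate) -> dict[str, int]:
    """Interval index per divider; a value equal to a split goes high."""
    out = {}
    for v, div in zip(point, gate.dividers):
        k = 0
        for s in div.values:
            if v >= s:
                k += 1
        out[div.id] = k
    return out


def evaluate_strategy_scalar(strategy, sample) -> dict[tuple, np.ndarray]:
    """Per-event scalar re-evaluation of a whole strategy.

    Channel/compensation/transform resolution is shared with the library
    (it is checked by its own oracles); all gate geometry and the
    hierarchy/boolean logic are recomputed here one event at a time.
    """
    ctx = _EvalContext(strategy, sample)
    n = sample.n_events
    memberships: dict[tuple, np.ndarray] = {ROOT: np.ones(n, dtype=bool)}

    for path, node in strategy._nodes.items():
        parent_mem = memberships[path[:-1]]
        mem = np.zeros(n, dtype=bool)
        if isinstance(node, _QuadrantCell):
            gate = strategy._nodes[node.owner_path]
            vals = np.column_stack([ctx.dim_values(d) for d in gate.dimensions])
            quad = next(q for q in gate.quadrants if q.id == node.name)
            for i in range(n):
                if not parent_mem[i]:
                    continue
                cell = quadrant_cell_of(vals[i], gate)
                mem[i] = all(cell[did] == k for did, k in quad.positions)
        elif isinstance(node, RectangleGate):
            vals = np.column_stack([ctx.dim_values(d) for d in node.dimensions])
            for i in range(n):
                mem[i] = parent_mem[i] and point_in_rectangle(vals[i], node)
        elif isinstance(node, PolygonGate):
            vals = np.column_stack([ctx.dim_values(d) for d in node.dimensions])
            verts = [tuple(v) for v in node.vertices]
            tol = 1e-12 * (max(abs(v) for xy in verts for v in xy) or 1.0)
            for i in range(n):
                mem[i] = parent_mem[i] and point_in_polygon(vals[i, 0], vals[i, 1],
                                                            verts, tol)
        elif isinstance(node, EllipsoidGate):
            vals = np.column_stack([ctx.dim_values(d) for d in node.dimensions])
            for i in range(n):
                mem[i] = parent_mem[i] and point_in_ellipsoid(vals[i], node)
        elif isinstance(node, QuadrantGate):
            mem = parent_mem.copy()        # container node covers its parent
        elif isinstance(node, BooleanGate):
            for i in range(n):
                bits = []
                for ref, complement in node.operands:
                    b = bool(memberships[tuple(ref)][i])
                    bits.append(not b if complement else b)
                if node.operator == "NOT":
                    v = not bits[0]
                elif node.operator == "AND":
                    v = all(bits)
                else:
                    v = any(bits)
                mem[i] = parent_mem[i] and v
        else:                               # pragma: no cover
            raise AssertionError(f"unexpected node {node!r}")
        memberships[path] = mem
    return memberships
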