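"""Gate geometry: dimensions, the five gate kinds, and membership tests.

Boundary semantics follow Gating-ML 2.0: gate boundaries belong to the gate
(closed intervals; polygon edges and vertices are inside).  Quadrant gates
use a >=-side tie rule — an event exactly on a divider value joins the cell
on the high side — which preserves the exact-partition invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GatingError, NonPositiveDefinite


@dataclass(frozen=True)
class Dimension:
    """Binding of one gate axis to (channel, compensation, transform).

    ``compensation_ref`` is ``"none"`` (raw events), ``"fcs"`` (the spillover
    stored in the sample's own metadata) or the id of a matrix registered on
    the strategy.  ``channel_ref`` is a $PnN name, or the id of a ratio
    transform registered on the strategy (derived dimension).
    """

    channel_ref: str
    compensation_ref: str = "none"
    transform_ref: str | None = None
    range_min: float | None = None
    range_max: float | None = None

    def __post_init__(self):
        if (self.range_min is not None and self.range_max is not None
                and not self.range_min < self.range_max):
            raise GatingError(f"dimension {self.channel_ref}: min {self.range_min} "
                              f"must be < max {self.range_max}")


@dataclass
class RectangleGate:
    """Axis-aligned box; absent bounds are unbounded; 1-D box = range gate."""

    name: str
    dimensions: list[Dimension]

    gate_type = "RectangleGate"

    def __post_init__(self):
        if not self.dimensions:
            raise GatingError(f"rectangle gate {self.name!r} needs >= 1 dimension")


@dataclass
class PolygonGate:
    """2-D polygon, even-odd fill rule, boundary inclusive."""

    name: str
    dimensions: list[Dimension]
    vertices: np.ndarray        # (k >= 3, 2), in the dimensions' (transformed) space

    gate_type = "PolygonGate"

    def __post_init__(self):
        if len(self.dimensions) != 2:
            raise GatingError(f"polygon gate {self.name!r} needs exactly 2 dimensions")
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise GatingError(f"polygon gate {self.name!r} needs >= 3 (x, y) vertices")
        # vertices must not all be collinear
        d = self.vertices[1:] - self.vertices[0]
        areas = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
        if np.all(np.abs(areas) == 0.0):
            raise GatingError(f"polygon gate {self.name!r}: vertices are collinear")


@dataclass
class EllipsoidGate:
    """Mahalanobis ball: (x - mu)^T C^-1 (x - mu) <= D^2."""

    name: str
    dimensions: list[Dimension]
    mean: np.ndarray
    covariance: np.ndarray
    distance_square: float

    gate_type = "EllipsoidGate"

    def __post_init__(self):
        k = len(self.dimensions)
        if k < 2:
            raise GatingError(f"ellipsoid gate {self.name!r} needs >= 2 dimensions")
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (k,) or self.covariance.shape != (k, k):
            raise GatingError(f"ellipsoid gate {self.name!r}: mean/covariance shape "
                              "inconsistent with dimension count")
        if not np.allclose(self.covariance, self.covariance.T):
            raise NonPositiveDefinite(f"ellipsoid gate {self.name!r}: covariance "
                                      "is not symmetric")
        try:
            np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError:
            raise NonPositiveDefinite(f"ellipsoid gate {self.name!r}: covariance "
                                      "is not positive-definite")
        if self.distance_square <= 0:
            raise GatingError(f"ellipsoid gate {self.name!r}: distance_square must be > 0")


@dataclass(frozen=True)
class Divider:
    """One quadrant divider: a dimension and ascending split values."""

    id: str
    dimension: Dimension
    values: tuple[float, ...]

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if not vals or any(b <= a for a, b in zip(vals, vals[1:])):
            raise GatingError(f"divider {self.id!r}: split values must be "
                              "non-empty and strictly ascending")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class Quadrant:
    """One named cell: an interval index (0-based) per divider id."""

    id: str
    positions: tuple[tuple[str, int], ...]     # (divider_id, interval index)


@dataclass
class QuadrantGate:
    """Partition of the parent by one or more divided axes."""

    name: str
    dividers: list[Divider]
    quadrants: list[Quadrant]

    gate_type = "QuadrantGate"

    def __post_init__(self):
        div_ids = [d.id for d in self.dividers]
        if len(set(div_ids)) != len(div_ids):
            raise GatingError(f"quadrant gate {self.name!r}: divider ids not unique")
        names = [q.id for q in self.quadrants]
        if len(set(names)) != len(names):
            raise GatingError(f"quadrant gate {self.name!r}: quadrant ids not unique")
        for q in self.quadrants:
            for div_id, k in q.positions:
                div = next((d for d in self.dividers if d.id == div_id), None)
                if div is None:
                    raise GatingError(f"quadrant {q.id!r} references unknown divider "
                                      f"{div_id!r}")
                if not 0 <= k <= len(div.values):
                    raise GatingError(f"quadrant {q.id!r}: interval index {k} out of "
                                      f"range for divider {div_id!r}")

    @property
    def dimensions(self) -> list[Dimension]:
        return [d.dimension for d in self.dividers]


@dataclass
class BooleanGate:
    """AND / OR / NOT over previously defined gate paths.

    Each operand is ``(path, complement)``: the referenced gate's membership
    vector, complemented first when the flag is set.
    """

    name: str
    operator: str                                  # AND | OR | NOT
    operands: list[tuple[tuple[str, ...], bool]]

    gate_type = "BooleanGate"

    def __post_init__(self):
        op = self.operator.upper()
        if op not in ("AND", "OR", "NOT"):
            raise GatingError(f"boolean gate {self.name!r}: operator must be "
                              "AND, OR or NOT")
        self.operator = op
        if op == "NOT" and len(self.operands) != 1:
            raise GatingError(f"boolean gate {self.name!r}: NOT takes exactly "
                              "one operand")
        if op in ("AND", "OR") and len(self.operands) < 1:
            raise GatingError(f"boolean gate {self.name!r}: needs >= 1 operand")
        self.operands = [(tuple(p), bool(c)) for p, c in self.operands]


Gate = RectangleGate | PolygonGate | EllipsoidGate | QuadrantGate | BooleanGate


# --------------------------------------------------------------------------
# Membership evaluation (vectorized)
# --------------------------------------------------------------------------

def eval_rectangle(values: np.ndarray, gate: RectangleGate) -> np.ndarray:
    """Closed-interval box test; ``values`` is [n_events x n_dims] aligned
    to ``gate.dimensions``."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    member = np.ones(values.shape[0], dtype=bool)
    for j, dim in enumerate(gate.dimensions):
        col = values[:, j]
        if dim.range_min is not None:
            member &= col >= dim.range_min
        if dim.range_max is not None:
            member &= col <= dim.range_max
    return member


def _on_segment(x, y, x1, y1, x2, y2, tol):
    cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
    within = ((x >= min(x1, x2) - tol) & (x <= max(x1, x2) + tol)
              & (y >= min(y1, y2) - tol) & (y <= max(y1, y2) + tol))
    return (np.abs(cross) <= tol) & within


def eval_polygon(values: np.ndarray, gate: PolygonGate) -> np.ndarray:
    """Even-odd crossing-number test with boundary points counted inside."""
    pts = np.atleast_2d(np.asarray(values, dtype=float))
    x, y = pts[:, 0], pts[:, 1]
    verts = gate.vertices
    scale = float(np.max(np.abs(verts))) or 1.0
    tol = 1e-12 * scale
    inside = np.zeros(len(pts), dtype=bool)
    boundary = np.zeros(len(pts), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        boundary |= _on_segment(x, y, x1, y1, x2, y2, tol)
        crosses = (y1 > y) != (y2 > y)
        if crosses.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (x < x_int)
    return inside | boundary


def eval_ellipsoid(values: np.ndarray, gate: EllipsoidGate) -> np.ndarray:
    """Member iff squared Mahalanobis distance <= distance_square."""
    pts = np.atleast_2d(np.asarray(values, dtype=float))
    diff = pts - gate.mean
    sol = np.linalg.solve(gate.covariance, diff.T)
    d2 = np.einsum("ij,ji->i", diff, sol)
    return d2 <= gate.distance_square


def eval_quadrant(values: np.ndarray, gate: QuadrantGate) -> dict[str, np.ndarray]:
    """Per-quadrant membership vectors.

    A value exactly equal to a split joins the interval on the >= side, so
    cells are pairwise disjoint and their union covers every event.
    """
    pts = np.atleast_2d(np.asarray(values, dtype=float))
    interval = {}
    for j, div in enumerate(gate.dividers):
        # index of the interval containing each value; ties go high
        interval[div.id] = np.searchsorted(np.asarray(div.values), pts[:, j],
                                           side="right")
    out = {}
    for q in gate.quadrants:
        member = np.ones(len(pts), dtype=bool)
        for div_id, k in q.positions:
            member &= interval[div_id] == k
        out[q.id] = member
    return out


def eval_boolean(gate: BooleanGate,
                 operand_vectors: list[np.ndarray]) -> np.ndarray:
    """Elementwise AND/OR/NOT; complement flags are applied by the caller's
    ordering of ``operand_vectors`` with :meth:`BooleanGate.operands`."""
    vecs = []
    for (path, complement), vec in zip(gate.operands, operand_vectors):
        vecs.append(~vec if complement else vec)
    if gate.operator == "NOT":
        return ~vecs[0]
    out = vecs[0].copy()
    for v in vecs[1:]:
        out = (out & v) if gate.operator == "AND" else (out | v)
    return out


def full_quadrant_grid(name: str, dividers: list[Divider]) -> QuadrantGate:
    """Convenience: the complete grid of cells over the given dividers,
    named by joining per-divider interval labels (e.g. "FL1-low FL2-high")."""
    from itertools import product

    ranges = [range(len(d.values) + 1) for d in dividers]
    labels = []
    for d in dividers:
        k = len(d.values)
        if k == 1:
            labels.append(["low", "high"])
        else:
            labels.append([f"i{j}" for j in range(k + 1)])
    quadrants = []
    for combo in product(*ranges):
        qid = " ".join(f"{d.id}-{labels[i][c]}" for i, (d, c)
                       in enumerate(zip(dividers, combo)))
        quadrants.append(Quadrant(qid, tuple((d.id, c) for d, c
                                             in zip(dividers, combo))))
    return QuadrantGate(name, dividers, quadrants)
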