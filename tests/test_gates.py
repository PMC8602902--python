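"""Gate geometry semantics and oracle equivalence for each gate kind."""

import numpy as np
import pytest

from cytogate.exceptions import GatingError, NonPositiveDefinite
from cytogate.gates import (
    BooleanGate,
    Dimension,
    Divider,
    EllipsoidGate,
    PolygonGate,
    RectangleGate,
    eval_boolean,
    eval_ellipsoid,
    eval_polygon,
    eval_quadrant,
    eval_rectangle,
    full_quadrant_grid,
)

from .oracles import point_in_ellipsoid, point_in_polygon, point_in_rectangle


class TestRectangle:
    def test_closed_interval_semantics(self):
        g = RectangleGate("r", [Dimension("x", range_min=0, range_max=10)])
        vals = np.array([[-1.0], [0.0], [5.0], [10.0], [11.0]])
        assert eval_rectangle(vals, g).tolist() == [False, True, True, True, False]

    def test_unbounded_side(self):
        g = RectangleGate("r", [Dimension("x", range_min=0)])
        assert eval_rectangle(np.array([[1e9]]), g)[0]

    def test_matches_scalar_oracle_on_random_boxes(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(-10, 10, (1000, 2))
        for _ in range(50):
            a = np.sort(rng.uniform(-10, 10, 2))
            b = np.sort(rng.uniform(-10, 10, 2))
            g = RectangleGate("r", [
                Dimension("x", range_min=a[0], range_max=a[1]),
                Dimension("y", range_min=b[0], range_max=b[1])])
            vec = eval_rectangle(pts, g)
            oracle = [point_in_rectangle(p, g) for p in pts]
            assert vec.tolist() == oracle


class TestPolygon:
    TRI = PolygonGate("t", [Dimension("x"), Dimension("y")],
                      [[0, 0], [4, 0], [0, 4]])

    def test_interior_and_exterior(self):
        out = eval_polygon(np.array([[1.0, 1.0], [5.0, 5.0]]), self.TRI)
        assert out.tolist() == [True, False]

    def test_edge_point_is_inside(self):
        # explicit on-segment case: midpoint of the bottom edge
        assert eval_polygon(np.array([[2.0, 0.0]]), self.TRI)[0]

    def test_vertex_is_inside(self):
        assert eval_polygon(np.array([[4.0, 0.0]]), self.TRI)[0]

    def test_vertex_order_irrelevant(self):
        rev = PolygonGate("t", self.TRI.dimensions, self.TRI.vertices[::-1])
        pts = np.random.default_rng(0).uniform(-1, 5, (500, 2))
        assert np.array_equal(eval_polygon(pts, self.TRI), eval_polygon(pts, rev))

    def test_self_intersecting_even_odd(self):
        bow = PolygonGate("b", [Dimension("x"), Dimension("y")],
                          [[0, 0], [2, 2], [2, 0], [0, 2]])
        # centre of the bow-tie crossing is on the boundary lines' overlap
        # region with even winding; points inside each lobe are members
        out = eval_polygon(np.array([[0.5, 1.0], [1.5, 1.0]]), bow)
        assert out.tolist() == [True, True]

    def test_matches_slow_winding_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            k = int(rng.integers(3, 8))
            verts = rng.uniform(-5, 5, (k, 2))
            try:
                g = PolygonGate("p", [Dimension("x"), Dimension("y")], verts)
            except GatingError:
                continue
            pts = rng.uniform(-6, 6, (1000, 2))
            vec = eval_polygon(pts, g)
            tol = 1e-12 * max(1.0, np.max(np.abs(verts)))
            oracle = [point_in_polygon(x, y, [tuple(v) for v in verts], tol)
                      for x, y in pts]
            assert vec.tolist() == oracle

    def test_collinear_vertices_rejected(self):
        with pytest.raises(GatingError):
            PolygonGate("c", [Dimension("x"), Dimension("y")],
                        [[0, 0], [1, 1], [2, 2]])


class TestEllipsoid:
    def test_identity_covariance(self):
        g = EllipsoidGate("e", [Dimension("x"), Dimension("y")],
                          [0, 0], np.eye(2), 1.0)
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 0.0]])
        assert eval_ellipsoid(pts, g).tolist() == [True, False, True]

    def test_anisotropic_hand_case(self):
        # C = diag(4, 1), D^2 = 1: (2,0) has d2 = 1 (in), (0,2) has d2 = 4
        g = EllipsoidGate("e", [Dimension("x"), Dimension("y")],
                          [0, 0], np.diag([4.0, 1.0]), 1.0)
        out = eval_ellipsoid(np.array([[2.0, 0.0], [0.0, 2.0]]), g)
        assert out.tolist() == [True, False]

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(0, 2, (1000, 2))
        for _ in range(20):
            a = rng.normal(size=(2, 2))
            cov = a @ a.T + 0.1 * np.eye(2)
            g = EllipsoidGate("e", [Dimension("x"), Dimension("y")],
                              rng.normal(size=2), cov, float(rng.uniform(0.5, 4)))
            vec = eval_ellipsoid(pts, g)
            assert vec.tolist() == [point_in_ellipsoid(p, g) for p in pts]

    def test_non_positive_definite_rejected(self):
        with pytest.raises(NonPositiveDefinite):
            EllipsoidGate("e", [Dimension("x"), Dimension("y")],
                          [0, 0], np.array([[1.0, 2.0], [2.0, 1.0]]), 1.0)


class TestQuadrant:
    def test_boundary_value_joins_high_side(self):
        g = full_quadrant_grid("q", [Divider("d", Dimension("x"), (0.0,))])
        cells = eval_quadrant(np.array([[-1.0], [0.0], [1.0]]), g)
        assert cells["d-low"].tolist() == [True, False, False]
        assert cells["d-high"].tolist() == [False, True, True]

    def test_two_dividers_partition(self):
        g = full_quadrant_grid("q", [Divider("dx", Dimension("x"), (0.0,)),
                                     Divider("dy", Dimension("y"), (0.0,))])
        pts = np.random.default_rng(1).normal(size=(500, 2))
        cells = eval_quadrant(pts, g)
        stacked = np.vstack(list(cells.values()))
        assert np.array_equal(stacked.sum(axis=0), np.ones(500))

    def test_three_way_split_covers_disjointly(self):
        g = full_quadrant_grid("q", [Divider("d", Dimension("x"), (-1.0, 1.0))])
        pts = np.linspace(-3, 3, 301).reshape(-1, 1)
        cells = eval_quadrant(pts, g)
        assert len(cells) == 3
        stacked = np.vstack(list(cells.values()))
        assert np.array_equal(stacked.sum(axis=0), np.ones(301))
        # interval assignment oracle
        counts = [int(c.sum()) for c in cells.values()]
        expect = [int((pts < -1).sum()), int(((pts >= -1) & (pts < 1)).sum()),
                  int((pts >= 1).sum())]
        assert counts == expect

    def test_split_values_must_ascend(self):
        with pytest.raises(GatingError):
            Divider("d", Dimension("x"), (1.0, 1.0))


class TestBoolean:
    def test_not_all_true(self):
        g = BooleanGate("n", "NOT", [(("root", "a"), False)])
        assert not eval_boolean(g, [np.ones(5, dtype=bool)]).any()

    def test_tautologies(self):
        rng = np.random.default_rng(4)
        a = rng.random(100) < 0.5
        g_and = BooleanGate("x", "AND", [(("root", "a"), False), (("root", "a"), True)])
        g_or = BooleanGate("y", "OR", [(("root", "a"), False), (("root", "a"), True)])
        assert not eval_boolean(g_and, [a, a]).any()
        assert eval_boolean(g_or, [a, a]).all()

    def test_de_morgan(self):
        rng = np.random.default_rng(5)
        a = rng.random(200) < 0.5
        b = rng.random(200) < 0.5
        lhs = ~eval_boolean(BooleanGate("x", "AND", [(("p",), False), (("q",), False)]),
                            [a, b])
        rhs = eval_boolean(BooleanGate("y", "OR", [(("p",), True), (("q",), True)]),
                           [a, b])
        assert np.array_equal(lhs, rhs)

    def test_not_requires_single_operand(self):
        with pytest.raises(GatingError):
            BooleanGate("n", "NOT", [(("a",), False), (("b",), False)])
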