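"""Hierarchical strategy evaluation: containment, editing, oracle
equivalence of full strategies, and transform/gate commutation."""

import numpy as np
import pytest

from cytogate import transforms as tr
from cytogate.exceptions import (
    ChannelMissing,
    DuplicatePath,
    RemoveBlocked,
    UnknownPath,
    UnresolvedReference,
)
from cytogate.gates import (
    BooleanGate,
    Dimension,
    PolygonGate,
    RectangleGate,
)
from cytogate.strategy import GatingStrategy, apply_gating_strategy
from cytogate.synth import three_population_sample

from .conftest import base_strategy, random_strategy
from .oracles import evaluate_strategy_scalar


class TestEvaluation:
    def test_root_only_strategy(self, small_sample):
        res = apply_gating_strategy(GatingStrategy(), small_sample)
        df = res.report
        assert len(df) == 1
        assert df.iloc[0]["count"] == small_sample.n_events
        assert df.iloc[0]["relative_percent"] == 100.0

    def test_known_population_fractions_recovered(self, tri_pop):
        sample, labels = tri_pop
        st = GatingStrategy()
        # level 1: all cells (loose scatter box); level 2: per-population gates
        st.add_gate(RectangleGate("Cells", [Dimension("FSC-A", range_min=0)]))
        st.add_gate(RectangleGate("P1", [
            Dimension("FL1-A", range_max=5000), Dimension("FL2-A", range_max=5000),
            Dimension("FSC-A", range_max=70000)]), ("root", "Cells"))
        st.add_gate(RectangleGate("P2", [
            Dimension("FL1-A", range_min=5000)]), ("root", "Cells"))
        st.add_gate(RectangleGate("P3", [
            Dimension("FL2-A", range_min=5000), Dimension("FL1-A", range_max=5000)]),
            ("root", "Cells"))
        res = apply_gating_strategy(st, sample)
        truth = [np.mean(labels == k) * 100 for k in range(3)]
        for name, target in zip(("P1", "P2", "P3"), truth):
            got = res.report.set_index("gate_name").loc[name, "relative_percent"]
            assert got == pytest.approx(target, abs=1.5)

    def test_empty_parent_yields_zero_percent(self, small_sample):
        st = GatingStrategy()
        st.add_gate(RectangleGate("none", [Dimension("FSC-A", range_min=1e12)]))
        st.add_gate(RectangleGate("child", [Dimension("SSC-A", range_min=0)]),
                    ("root", "none"))
        df = apply_gating_strategy(st, small_sample).report.set_index("gate_name")
        assert df.loc["none", "count"] == 0
        assert df.loc["child", "count"] == 0
        assert df.loc["child", "relative_percent"] == 0.0

    def test_missing_channel_raises(self, small_sample):
        st = GatingStrategy()
        st.add_gate(RectangleGate("g", [Dimension("CD99-A", range_min=0)]))
        with pytest.raises(ChannelMissing):
            apply_gating_strategy(st, small_sample)

    def test_unresolved_transform_raises(self, small_sample):
        st = GatingStrategy()
        st.add_gate(RectangleGate("g", [Dimension("FSC-A", transform_ref="ghost",
                                                  range_min=0)]))
        with pytest.raises(UnresolvedReference):
            apply_gating_strategy(st, small_sample)

    def test_determinism(self, small_sample):
        st = random_strategy(np.random.default_rng(0), 5)
        a = apply_gating_strategy(st, small_sample)
        b = apply_gating_strategy(st, small_sample)
        for path, vec in a.memberships.items():
            assert np.array_equal(vec, b.memberships[path])


class TestInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_monotone_containment(self, seed, small_sample):
        st = random_strategy(np.random.default_rng(seed), 5)
        res = apply_gating_strategy(st, small_sample)
        for path, vec in res.memberships.items():
            if len(path) > 1:
                parent = res.memberships[path[:-1]]
                assert not (vec & ~parent).any()

    @pytest.mark.parametrize("seed", range(6))
    def test_scalar_oracle_reproduces_every_vector(self, seed):
        sample, _ = three_population_sample(1000, seed=100 + seed)
        st = random_strategy(np.random.default_rng(seed), 5)
        res = apply_gating_strategy(st, sample)
        oracle = evaluate_strategy_scalar(st, sample)
        for path, vec in oracle.items():
            assert np.array_equal(res.memberships[path], vec), path

    def test_transform_gate_commutation(self, small_sample):
        # gating transformed values with transformed bounds == gating raw
        # values with inverse-transformed bounds
        spec = tr.logicle(262144, 0.5, 4.5, 0, id="lgl")
        lo_t, hi_t = 0.3, 0.8
        lo_raw = float(tr.invert_transform(lo_t, spec))
        hi_raw = float(tr.invert_transform(hi_t, spec))

        st1 = GatingStrategy()
        st1.add_transform(spec)
        st1.add_gate(RectangleGate("g", [Dimension("FL1-A", transform_ref="lgl",
                                                   range_min=lo_t, range_max=hi_t)]))
        st2 = GatingStrategy()
        st2.add_gate(RectangleGate("g", [Dimension("FL1-A", range_min=lo_raw,
                                                   range_max=hi_raw)]))
        a = apply_gating_strategy(st1, small_sample).membership(("root", "g"))
        b = apply_gating_strategy(st2, small_sample).membership(("root", "g"))
        assert np.array_equal(a, b)

    def test_polygon_commutation(self, small_sample):
        # polygon edges are straight lines only in the space they were
        # drawn in, so commutation holds for per-axis affine transforms
        # (nonlinear maps bend the edges); rectangles commute under any
        # monotone transform and are checked with logicle above
        spec = tr.linear(262144, 0, id="lin")
        verts_t = np.array([[0.05, 0.05], [0.9, 0.1], [0.4, 0.9]])
        verts_raw = np.column_stack([tr.invert_transform(verts_t[:, 0], spec),
                                     tr.invert_transform(verts_t[:, 1], spec)])
        st1 = GatingStrategy()
        st1.add_transform(spec)
        st1.add_gate(PolygonGate("g", [Dimension("FL1-A", transform_ref="lin"),
                                       Dimension("FL2-A", transform_ref="lin")],
                                 verts_t))
        st2 = GatingStrategy()
        st2.add_gate(PolygonGate("g", [Dimension("FL1-A"), Dimension("FL2-A")],
                                 verts_raw))
        a = apply_gating_strategy(st1, small_sample).membership(("root", "g"))
        b = apply_gating_strategy(st2, small_sample).membership(("root", "g"))
        # monotone transforms preserve sidedness except exactly on the
        # (measure-zero) boundary; require exact agreement here
        assert np.array_equal(a, b)


class TestEditing:
    def test_duplicate_sibling_rejected(self):
        st = base_strategy()
        st.add_gate(RectangleGate("A", [Dimension("FSC-A", range_min=0)]))
        with pytest.raises(DuplicatePath):
            st.add_gate(RectangleGate("A", [Dimension("SSC-A", range_min=0)]))

    def test_remove_leaf(self):
        st = base_strategy()
        st.add_gate(RectangleGate("A", [Dimension("FSC-A", range_min=0)]))
        st.add_gate(RectangleGate("B", [Dimension("SSC-A", range_min=0)]),
                    ("root", "A"))
        st.remove_gate(("root", "A", "B"))
        assert st.gate_paths == [("root", "A")]

    def test_remove_subtree(self):
        st = base_strategy()
        st.add_gate(RectangleGate("A", [Dimension("FSC-A", range_min=0)]))
        st.add_gate(RectangleGate("B", [Dimension("SSC-A", range_min=0)]),
                    ("root", "A"))
        st.remove_gate(("root", "A"))
        assert st.gate_paths == []

    def test_remove_referenced_gate_blocked(self):
        st = base_strategy()
        st.add_gate(RectangleGate("A", [Dimension("FSC-A", range_min=0)]))
        st.add_gate(BooleanGate("N", "NOT", [(("root", "A"), False)]))
        with pytest.raises(RemoveBlocked):
            st.remove_gate(("root", "A"))
        st.remove_gate(("root", "N"))       # removing the referrer first is fine
        st.remove_gate(("root", "A"))

    def test_boolean_forward_reference_rejected(self):
        st = base_strategy()
        with pytest.raises(UnresolvedReference):
            st.add_gate(BooleanGate("N", "NOT", [(("root", "later"), False)]))

    def test_replace_gate_changes_result(self, small_sample):
        st = base_strategy()
        st.add_gate(RectangleGate("A", [Dimension("FSC-A", range_min=1e12)]))
        assert apply_gating_strategy(st, small_sample).count(("root", "A")) == 0
        st.replace_gate(("root", "A"),
                        RectangleGate("A", [Dimension("FSC-A", range_min=0)]))
        assert apply_gating_strategy(st, small_sample).count(("root", "A")) == \
            small_sample.n_events

    def test_unknown_path(self):
        st = base_strategy()
        with pytest.raises(UnknownPath):
            st.remove_gate(("root", "ghost"))


class TestTreeText:
    def test_single_gate_two_lines(self):
        st = GatingStrategy()
        st.add_gate(RectangleGate("A", [Dimension("FSC-A", range_min=0)]))
        assert st.gate_tree_text() == "root\n  A"

    def test_line_count_tracks_gates(self):
        st = GatingStrategy()
        st.add_gate(RectangleGate("A", [Dimension("FSC-A", range_min=0)]))
        st.add_gate(RectangleGate("B", [Dimension("SSC-A", range_min=0)]),
                    ("root", "A"))
        assert len(st.gate_tree_text().splitlines()) == 3

    def test_insertion_order_is_stable(self):
        st = GatingStrategy()
        for name in ("C", "A", "B"):
            st.add_gate(RectangleGate(name, [Dimension("FSC-A", range_min=0)]))
        assert st.gate_tree_text().splitlines()[1:] == ["  C", "  A", "  B"]
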