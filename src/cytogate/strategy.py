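"""Hierarchical gating strategies and their evaluation against samples.

A :class:`GatingStrategy` holds registries of transforms and spillover
matrices plus a rooted tree of gates addressed by full path, e.g.
``("root", "Cells", "Lymphocytes")``.  Paths rather than bare names remove
the ambiguity of same-named gates at different levels.

Evaluation follows the Gating-ML model: events enter from the scaled
("raw") state and each gate dimension independently selects its
compensation and transform; whole samples are never pre-transformed.
Membership vectors are computed over all events and intersected with the
parent's membership, which is equivalent to evaluating on the parent
subset for purely geometric gates and keeps every vector full length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compensation import SpilloverMatrix, apply_compensation, spillover_from_sample
from .exceptions import (
    ChannelMissing,
    DuplicatePath,
    GatingError,
    RemoveBlocked,
    UnknownPath,
    UnresolvedReference,
)
from .fcs_io import Sample
from .gates import (
    BooleanGate,
    EllipsoidGate,
    Gate,
    PolygonGate,
    QuadrantGate,
    RectangleGate,
    eval_boolean,
    eval_ellipsoid,
    eval_polygon,
    eval_quadrant,
    eval_rectangle,
)
from .transforms import TransformSpec, apply_ratio, apply_transform

ROOT = ("root",)

_UNCOMP = ("none", "uncompensated", None, "")


@dataclass
class _QuadrantCell:
    """Virtual tree node for one cell of a QuadrantGate."""

    name: str
    owner_path: tuple[str, ...]

    gate_type = "Quadrant"


class GatingStrategy:
    """Transform/compensation registries plus a rooted tree of gates."""

    def __init__(self):
        self.transforms: dict[str, TransformSpec] = {}
        self.comp_matrices: dict[str, SpilloverMatrix] = {}
        self._nodes: dict[tuple[str, ...], object] = {}   # insertion-ordered

    # -- registries ---------------------------------------------------------

    def add_transform(self, spec: TransformSpec):
        if not spec.id:
            raise GatingError("transform spec needs a non-empty id")
        self.transforms[spec.id] = spec

    def add_comp_matrix(self, matrix: SpilloverMatrix):
        if not matrix.id:
            raise GatingError("spillover matrix needs a non-empty id")
        self.comp_matrices[matrix.id] = matrix

    # -- tree editing -------------------------------------------------------

    @property
    def gate_paths(self) -> list[tuple[str, ...]]:
        return list(self._nodes)

    def get_gate(self, path):
        path = tuple(path)
        if path not in self._nodes:
            raise UnknownPath(f"no gate at path {'/'.join(path)}")
        node = self._nodes[path]
        if isinstance(node, _QuadrantCell):
            return self._nodes[node.owner_path]
        return node

    def add_gate(self, gate: Gate, parent_path=ROOT):
        parent_path = tuple(parent_path)
        if parent_path != ROOT and parent_path not in self._nodes:
            raise UnknownPath(f"parent path {'/'.join(parent_path)} does not exist")
        path = parent_path + (gate.name,)
        if path in self._nodes:
            raise DuplicatePath(f"a gate already exists at {'/'.join(path)}")
        if isinstance(gate, BooleanGate):
            for ref, _comp in gate.operands:
                if tuple(ref) != ROOT and tuple(ref) not in self._nodes:
                    raise UnresolvedReference(
                        f"boolean gate {gate.name!r} references undefined path "
                        f"{'/'.join(ref)} (forward references are rejected)")
        self._nodes[path] = gate
        if isinstance(gate, QuadrantGate):
            for q in gate.quadrants:
                cell_path = path + (q.id,)
                if cell_path in self._nodes:
                    raise DuplicatePath(f"quadrant cell collides at {'/'.join(cell_path)}")
                self._nodes[cell_path] = _QuadrantCell(q.id, path)
        return path

    def _subtree(self, path):
        path = tuple(path)
        return [p for p in self._nodes if p[:len(path)] == path]

    def remove_gate(self, path):
        path = tuple(path)
        if path not in self._nodes:
            raise UnknownPath(f"no gate at path {'/'.join(path)}")
        doomed = set(self._subtree(path))
        for p, node in self._nodes.items():
            if p in doomed or not isinstance(node, BooleanGate):
                continue
            for ref, _comp in node.operands:
                if tuple(ref) in doomed:
                    raise RemoveBlocked(
                        f"cannot remove {'/'.join(path)}: boolean gate at "
                        f"{'/'.join(p)} references {'/'.join(ref)}")
        for p in doomed:
            del self._nodes[p]

    def replace_gate(self, path, gate: Gate):
        path = tuple(path)
        if path not in self._nodes:
            raise UnknownPath(f"no gate at path {'/'.join(path)}")
        if path[-1] != gate.name:
            raise GatingError("replacement gate must keep the same name "
                              f"({path[-1]!r})")
        old = self._nodes[path]
        if isinstance(old, _QuadrantCell):
            raise GatingError("quadrant cells cannot be replaced individually")
        if isinstance(old, QuadrantGate) or isinstance(gate, QuadrantGate):
            # swap including cells: remove + re-add subtree root only
            if self._subtree(path) != [path] + [path + (q.id,) for q in
                                               getattr(old, "quadrants", [])]:
                raise GatingError("cannot replace a quadrant gate that has "
                                  "child gates under its cells")
            self.remove_gate(path)
            self.add_gate(gate, path[:-1])
        else:
            self._nodes[path] = gate

    def gate_tree_text(self) -> str:
        """ASCII rendering: "root" plus one line per gate, two-space indent
        per level, insertion order."""
        lines = ["root"]
        for path in self._nodes:
            lines.append("  " * (len(path) - 1) + path[-1])
        return "\n".join(lines)

    def copy(self) -> "GatingStrategy":
        import copy as _copy
        return _copy.deepcopy(self)

    def __repr__(self):
        n_gates = sum(1 for v in self._nodes.values()
                      if not isinstance(v, _QuadrantCell))
        return (f"GatingStrategy({n_gates} gates, {len(self.transforms)} "
                f"transforms, {len(self.comp_matrices)} matrices)")


class GatingResults:
    """Per-gate-path membership vectors and the derived summary table."""

    def __init__(self, sample_id: str, n_events: int):
        self.sample_id = sample_id
        self.n_events = n_events
        self.memberships: dict[tuple[str, ...], np.ndarray] = {}
        self._rows: list[dict] = []

    def add(self, path, gate_type: str, membership: np.ndarray, parent_count: int):
        count = int(membership.sum())
        self.memberships[tuple(path)] = membership
        rel = 100.0 * count / parent_count if parent_count > 0 else 0.0
        absf = 100.0 * count / self.n_events if self.n_events > 0 else 0.0
        self._rows.append({
            "sample": self.sample_id,
            "gate_path": "/".join(path),
            "gate_name": path[-1],
            "gate_type": gate_type,
            "level": len(path) - 1,
            "count": count,
            "relative_percent": rel,
            "absolute_percent": absf,
        })

    def membership(self, path) -> np.ndarray:
        path = tuple(path)
        if path not in self.memberships:
            raise UnknownPath(f"no results for path {'/'.join(path)}")
        return self.memberships[path]

    def count(self, path) -> int:
        return int(self.membership(path).sum())

    @property
    def report(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=[
            "sample", "gate_path", "gate_name", "gate_type", "level",
            "count", "relative_percent", "absolute_percent"])

    def to_csv(self, path=None) -> str:
        df = self.report[["sample", "gate_path", "gate_name", "gate_type",
                          "count", "relative_percent", "absolute_percent"]]
        out = df.to_csv(index=False, lineterminator="\r\n")
        if path is not None:
            with open(path, "w", newline="") as fh:
                fh.write(out)
        return out


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

class _EvalContext:
    """Caches per-compensation-ref event matrices for one sample."""

    def __init__(self, strategy: GatingStrategy, sample: Sample):
        self.strategy = strategy
        self.sample = sample
        self._comp_cache: dict[str, np.ndarray] = {}
        self.chan_index = {p.pnn: i for i, p in enumerate(sample.params)}

    def comp_events(self, ref) -> np.ndarray:
        key = ref if ref not in _UNCOMP else "none"
        if key in self._comp_cache:
            return self._comp_cache[key]
        if key == "none":
            ev = self.sample.events_raw
        else:
            if key in ("fcs", "FCS"):
                spill = spillover_from_sample(self.sample)
            elif key in self.strategy.comp_matrices:
                spill = self.strategy.comp_matrices[key]
            else:
                raise UnresolvedReference(f"compensation ref {ref!r} does not resolve")
            cmap = {}
            for det in spill.detectors:
                if det not in self.chan_index:
                    raise ChannelMissing(f"spill detector {det!r} missing from "
                                         f"sample {self.sample.sample_id!r}")
                cmap[det] = self.chan_index[det]
            ev = apply_compensation(self.sample.events_raw, spill, cmap)
        self._comp_cache[key] = ev
        return ev

    def dim_values(self, dim) -> np.ndarray:
        base = self.comp_events(dim.compensation_ref)
        spec = None
        if dim.channel_ref in self.strategy.transforms and \
                self.strategy.transforms[dim.channel_ref].kind == "ratio":
            rspec = self.strategy.transforms[dim.channel_ref]
            vals = apply_ratio(base, self.chan_index, rspec)
        elif dim.channel_ref in self.chan_index:
            vals = base[:, self.chan_index[dim.channel_ref]]
        else:
            raise ChannelMissing(f"channel {dim.channel_ref!r} missing from "
                                 f"sample {self.sample.sample_id!r}")
        if dim.transform_ref:
            if dim.transform_ref not in self.strategy.transforms:
                raise UnresolvedReference(f"transform ref {dim.transform_ref!r} "
                                          "does not resolve")
            spec = self.strategy.transforms[dim.transform_ref]
            vals = apply_transform(vals, spec)
        return np.asarray(vals, dtype=float)

    def gate_values(self, gate) -> np.ndarray:
        return np.column_stack([self.dim_values(d) for d in gate.dimensions])


def apply_gating_strategy(strategy: GatingStrategy, sample: Sample) -> GatingResults:
    """Evaluate every gate of the strategy against one sample.

    Gates are visited in insertion order, which is a valid topological
    order: parents are inserted before children and boolean gates may only
    reference already-inserted paths.  Deterministic for fixed inputs.
    """
    ctx = _EvalContext(strategy, sample)
    n = sample.n_events
    results = GatingResults(sample.sample_id, n)
    memberships: dict[tuple[str, ...], np.ndarray] = {ROOT: np.ones(n, dtype=bool)}
    results.add(ROOT, "root", memberships[ROOT], n)
    quad_cells: dict[tuple[str, ...], np.ndarray] = {}

    for path, node in strategy._nodes.items():
        parent = path[:-1]
        parent_mem = memberships[parent]
        parent_count = int(parent_mem.sum())

        if isinstance(node, _QuadrantCell):
            geom = quad_cells[path]
        elif isinstance(node, RectangleGate):
            geom = eval_rectangle(ctx.gate_values(node), node)
        elif isinstance(node, PolygonGate):
            geom = eval_polygon(ctx.gate_values(node), node)
        elif isinstance(node, EllipsoidGate):
            geom = eval_ellipsoid(ctx.gate_values(node), node)
        elif isinstance(node, QuadrantGate):
            cells = eval_quadrant(ctx.gate_values(node), node)
            for q in node.quadrants:
                quad_cells[path + (q.id,)] = cells[q.id]
            geom = np.ones(n, dtype=bool)      # container node = parent
        elif isinstance(node, BooleanGate):
            vecs = [memberships[tuple(ref)] for ref, _c in node.operands]
            geom = eval_boolean(node, vecs)
        else:                                  # pragma: no cover
            raise GatingError(f"unknown node type at {'/'.join(path)}")

        mem = geom & parent_mem
        memberships[path] = mem
        results.add(path, getattr(node, "gate_type", type(node).__name__),
                    mem, parent_count)
    return results
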