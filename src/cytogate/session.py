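"""Multi-sample analysis sessions: groups, templates, overrides, reports.

A :class:`Session` holds samples plus named sample groups; each group has a
single template :class:`GatingStrategy` and optional per-sample gate
overrides keyed by (sample id, gate path).  Results are cached per
(group, sample) and the cache is invalidated on any edit.

Per-sample overrides exist only in memory here; workspace import/export
(:mod:`cytogate.wsp`) is template-only.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import fcs_io
from .exceptions import DuplicateSample, SessionError, UnknownPath
from .fcs_io import Sample
from .gates import Gate
from .strategy import GatingResults, GatingStrategy, apply_gating_strategy

log = logging.getLogger(__name__)


@dataclass
class SampleGroup:
    name: str
    members: list[str] = field(default_factory=list)
    template: GatingStrategy = field(default_factory=GatingStrategy)
    overrides: dict[tuple[str, tuple[str, ...]], Gate] = field(default_factory=dict)


class Session:
    """A collection of samples and gated sample groups."""

    def __init__(self):
        self.samples: dict[str, Sample] = {}
        self.groups: dict[str, SampleGroup] = {}
        self._cache: dict[tuple[str, str], GatingResults] = {}

    # -- membership ---------------------------------------------------------

    def create_group(self, name: str, template: GatingStrategy | None = None) -> SampleGroup:
        if name in self.groups:
            raise SessionError(f"group {name!r} already exists")
        g = SampleGroup(name, template=template or GatingStrategy())
        self.groups[name] = g
        self._cache.clear()
        return g

    def add_samples(self, samples, group: str | None = None):
        """Add Samples (or FCS paths) to the session, optionally into a group.

        A sample already present may be assigned to further groups but is
        stored once; re-adding a *different* sample under an existing id
        raises :class:`DuplicateSample`.
        """
        if isinstance(samples, (str, os.PathLike, Sample)):
            samples = [samples]
        added = []
        for item in samples:
            smp = item if isinstance(item, Sample) else fcs_io.read_fcs(item)
            if smp.sample_id in self.samples:
                if self.samples[smp.sample_id] is not smp and not isinstance(item, (str, os.PathLike)):
                    raise DuplicateSample(f"sample id {smp.sample_id!r} already "
                                          "present with a different object")
                smp = self.samples[smp.sample_id]
            else:
                self.samples[smp.sample_id] = smp
            added.append(smp.sample_id)
        if group is not None:
            if group not in self.groups:
                self.create_group(group)
            g = self.groups[group]
            for sid in added:
                if sid not in g.members:
                    g.members.append(sid)
        self._cache.clear()
        return added

    def set_template(self, group: str, template: GatingStrategy):
        self._group(group).template = template
        self._cache.clear()

    def _group(self, name: str) -> SampleGroup:
        if name not in self.groups:
            raise SessionError(f"no group named {name!r}")
        return self.groups[name]

    # -- per-sample overrides ------------------------------------------------

    def set_gate_override(self, group: str, sample_id: str, gate_path, gate: Gate):
        g = self._group(group)
        if sample_id not in g.members:
            raise SessionError(f"sample {sample_id!r} is not a member of group "
                               f"{group!r}")
        path = tuple(gate_path)
        if path not in g.template._nodes:
            raise UnknownPath(f"template has no gate at {'/'.join(path)}")
        g.overrides[(sample_id, path)] = gate
        self._cache.clear()

    def clear_gate_override(self, group: str, sample_id: str, gate_path):
        g = self._group(group)
        g.overrides.pop((sample_id, tuple(gate_path)), None)
        self._cache.clear()

    def _strategy_for(self, group: SampleGroup, sample_id: str) -> GatingStrategy:
        ovr = {p: gate for (sid, p), gate in group.overrides.items()
               if sid == sample_id}
        if not ovr:
            return group.template
        strat = group.template.copy()
        for path, gate in ovr.items():
            strat.replace_gate(path, gate)
        return strat

    # -- analysis -------------------------------------------------------------

    def analyze_sample(self, group: str, sample_id: str) -> GatingResults:
        key = (group, sample_id)
        if key in self._cache:
            return self._cache[key]
        g = self._group(group)
        if sample_id not in g.members:
            raise SessionError(f"sample {sample_id!r} not in group {group!r}")
        res = apply_gating_strategy(self._strategy_for(g, sample_id),
                                    self.samples[sample_id])
        self._cache[key] = res
        return res

    def analyze_group(self, group: str) -> dict[str, GatingResults]:
        g = self._group(group)
        return {sid: self.analyze_sample(group, sid) for sid in g.members}

    def report(self, group: str, out_path=None,
               join_table: pd.DataFrame | str | None = None) -> pd.DataFrame:
        """Long-format results table; optionally joined with a CBC table.

        ``join_table`` (DataFrame or CSV path) must carry a sample-id column
        (``sample``) and a ``cells_per_ul`` column; the derived column is
        absolute_count_per_ul = absolute_percent / 100 * cells_per_ul.
        Samples missing from the join table keep an empty derived column
        (with a warning); the base columns are never altered.
        """
        frames = [res.report.drop(columns=["level"])
                  for res in self.analyze_group(group).values()]
        df = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["sample", "gate_path", "gate_name",
                                         "gate_type", "count",
                                         "relative_percent", "absolute_percent"]))
        if join_table is not None:
            if isinstance(join_table, (str, os.PathLike)):
                join_table = pd.read_csv(join_table)
            cbc = join_table.set_index("sample")["cells_per_ul"]
            missing = sorted(set(df["sample"]) - set(cbc.index))
            if missing:
                log.warning("report join: no cells_per_ul entry for sample(s) %s",
                            ", ".join(missing))
            conc = df["sample"].map(cbc)
            df["absolute_count_per_ul"] = df["absolute_percent"] / 100.0 * conc
        if out_path is not None:
            df.to_csv(out_path, index=False, lineterminator="\r\n")
        return df

    def export_gated_events(self, group: str, gate_path, source: str = "raw",
                            out_dir=None, fmt: str = "fcs") -> dict[str, object]:
        """Write per-sample files containing only the gate's member events.

        Returns {sample_id: output path} (or the gated Samples when
        ``out_dir`` is None).  ``fmt`` is "fcs" or "csv".
        """
        g = self._group(group)
        path = tuple(gate_path)
        out = {}
        for sid in g.members:
            res = self.analyze_sample(group, sid)
            member = res.membership(path)
            smp = self.samples[sid]
            events = smp.get_events(source)[member]
            gated = fcs_io.create_sample_from_matrix(
                events, smp.channel_names,
                labels=[p.pns for p in smp.params] if any(p.pns for p in smp.params) else None,
                sample_id=f"{sid}-gated")
            if out_dir is None:
                out[sid] = gated
                continue
            safe = "".join(c if c.isalnum() or c in "._-" else "_" for c in sid)
            if fmt == "fcs":
                dest = os.path.join(out_dir, f"{safe}_gated.fcs")
                fcs_io.write_fcs(gated, "raw", dest)
            elif fmt == "csv":
                dest = os.path.join(out_dir, f"{safe}_gated.csv")
                fcs_io.export_csv(gated, "raw", dest)
            else:
                raise ValueError(f"fmt must be 'fcs' or 'csv', got {fmt!r}")
            out[sid] = dest
        return out
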