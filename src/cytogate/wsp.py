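"""FlowJo 10 workspace (WSP) import/export — documented subset.

The supported surface is template-only per sample group: sample entries
(file reference + keywords), groups with member lists, compensation
matrices, transform declarations, and one template gate tree per group.
Per-sample gate customizations inside a WSP are rejected with a clear
diagnostic; legacy JO files are out of scope.

Gate coordinates are stored in untransformed (channel/data) space, the
convention FlowJo uses, and converted on the fly with each dimension's
inverse/forward transform chain; for the table-driven FlowJo biexponential
this conversion is accurate to about 1e-4 of full scale.  Ellipsoid gates
are the exception: their mean/covariance quadratic form is only defined in
transformed space and is stored there unchanged.

Reading foreign workspaces is best-effort: unsupported node types are
collected into a warnings list rather than being fatal, except where they
would silently change results (per-sample gates).
"""

from __future__ import annotations

import os
from urllib.parse import unquote, urlparse

import numpy as np
from lxml import etree

from . import fcs_io
from .compensation import SpilloverMatrix
from .exceptions import (
    NotExpressible,
    SampleFileMissing,
    SchemaViolation,
    UnsupportedElement,
    UnsupportedWorkspaceVersion,
)
from .gates import (
    BooleanGate,
    Dimension,
    Divider,
    EllipsoidGate,
    PolygonGate,
    Quadrant,
    QuadrantGate,
    RectangleGate,
)
from .gatingml import NS_D, NS_G, NS_T, NS_X, _d, _g, _num, _t, path_to_id
from .session import Session
from .strategy import ROOT, GatingStrategy
from .transforms import TransformSpec, apply_transform, invert_transform

NSMAP = {"gating": NS_G, "transforms": NS_T, "data-type": NS_D, "cg": NS_X}

FLOWJO_VERSION = "10.8.1"

_COMP_OUT = {"none": "uncompensated", "fcs": "FCS", None: "uncompensated",
             "": "uncompensated"}
_COMP_IN = {"uncompensated": "none", "FCS": "fcs"}

#: WSP-expressible transform kinds (ratio derived parameters are not)
_WSP_KINDS = ("linear", "log", "asinh", "logicle", "hyperlog", "flowjo_biex")


def _cg(tag):
    return f"{{{NS_X}}}{tag}"


# --------------------------------------------------------------------------
# coordinate conversion helpers
# --------------------------------------------------------------------------

def _to_data_space(value, dim: Dimension, strategy: GatingStrategy):
    if dim.transform_ref is None or value is None:
        return value
    spec = strategy.transforms[dim.transform_ref]
    return float(np.asarray(invert_transform(value, spec)))


def _to_scale_space(value, dim: Dimension, strategy: GatingStrategy):
    if dim.transform_ref is None or value is None:
        return value
    spec = strategy.transforms[dim.transform_ref]
    return float(np.asarray(apply_transform(value, spec)))


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------

def _write_wsp_transform(parent, spec: TransformSpec):
    if spec.kind not in _WSP_KINDS:
        raise NotExpressible(f"transform {spec.id!r} of kind {spec.kind!r} "
                             "cannot be expressed in a FlowJo workspace")
    if spec.kind == "linear":
        el = etree.SubElement(parent, _t("linear"),
                              {_t("minRange"): _num(-spec.A),
                               _t("maxRange"): _num(spec.T)})
    elif spec.kind == "log":
        el = etree.SubElement(parent, _t("log"),
                              {_t("decades"): _num(spec.M),
                               _t("maxRange"): _num(spec.T)})
    elif spec.kind == "asinh":
        el = etree.SubElement(parent, _t("fasinh"),
                              {_t("T"): _num(spec.T), _t("M"): _num(spec.M),
                               _t("A"): _num(spec.A)})
    elif spec.kind in ("logicle", "hyperlog"):
        el = etree.SubElement(parent, _t(spec.kind),
                              {_t("T"): _num(spec.T), _t("W"): _num(spec.W),
                               _t("M"): _num(spec.M), _t("A"): _num(spec.A)})
    else:   # flowjo_biex
        el = etree.SubElement(parent, _t("biex"),
                              {_t("maxRange"): _num(spec.max_value),
                               _t("pos"): _num(spec.pos_decades),
                               _t("width"): _num(spec.width_basis),
                               _t("neg"): _num(spec.neg_decades),
                               _t("length"): "256"})
    el.set(_cg("id"), spec.id)
    return el


def _write_wsp_dimension(parent, dim: Dimension, strategy: GatingStrategy,
                         with_bounds: bool):
    attrs = {_g("compensation-ref"): _COMP_OUT.get(dim.compensation_ref,
                                                   dim.compensation_ref)}
    if dim.transform_ref:
        attrs[_g("transformation-ref")] = dim.transform_ref
    if with_bounds:
        if dim.range_min is not None:
            attrs[_g("min")] = _num(_to_data_space(dim.range_min, dim, strategy))
        if dim.range_max is not None:
            attrs[_g("max")] = _num(_to_data_space(dim.range_max, dim, strategy))
    el = etree.SubElement(parent, _g("dimension"), attrs)
    if dim.channel_ref in strategy.transforms and \
            strategy.transforms[dim.channel_ref].kind == "ratio":
        raise NotExpressible("ratio-transform gate dimensions cannot be "
                             "expressed in a FlowJo workspace")
    etree.SubElement(el, _d("fcs-dimension"), {_d("name"): dim.channel_ref})


def _write_gate_element(parent, node, gpath, strategy, id_of):
    gid = path_to_id(gpath)
    attrs = {_g("id"): gid}

    if isinstance(node, RectangleGate):
        el = etree.SubElement(parent, _g("RectangleGate"), attrs)
        for dim in node.dimensions:
            _write_wsp_dimension(el, dim, strategy, with_bounds=True)
    elif isinstance(node, PolygonGate):
        el = etree.SubElement(parent, _g("PolygonGate"), attrs)
        for dim in node.dimensions:
            _write_wsp_dimension(el, dim, strategy, with_bounds=False)
        for x, y in node.vertices:
            v = etree.SubElement(el, _g("vertex"))
            etree.SubElement(v, _g("coordinate"),
                             {_d("value"): _num(_to_data_space(x, node.dimensions[0], strategy))})
            etree.SubElement(v, _g("coordinate"),
                             {_d("value"): _num(_to_data_space(y, node.dimensions[1], strategy))})
    elif isinstance(node, EllipsoidGate):
        # quadratic form stays in transformed space (see module docstring)
        el = etree.SubElement(parent, _g("EllipsoidGate"), attrs)
        for dim in node.dimensions:
            _write_wsp_dimension(el, dim, strategy, with_bounds=False)
        mean = etree.SubElement(el, _g("mean"))
        for v in node.mean:
            etree.SubElement(mean, _g("coordinate"), {_d("value"): _num(v)})
        cov = etree.SubElement(el, _g("covarianceMatrix"))
        for row in node.covariance:
            r = etree.SubElement(cov, _g("row"))
            for v in row:
                etree.SubElement(r, _g("entry"), {_d("value"): _num(v)})
        etree.SubElement(el, _g("distanceSquare"),
                         {_d("value"): _num(node.distance_square)})
    elif isinstance(node, QuadrantGate):
        el = etree.SubElement(parent, _g("QuadrantGate"), attrs)
        for div in node.dividers:
            dv = etree.SubElement(el, _g("divider"))
            dv.set(_g("id"), f"{gid}.{div.id}")
            dv.set(_cg("name"), div.id)
            dv.set(_g("compensation-ref"),
                   _COMP_OUT.get(div.dimension.compensation_ref,
                                 div.dimension.compensation_ref))
            if div.dimension.transform_ref:
                dv.set(_g("transformation-ref"), div.dimension.transform_ref)
            etree.SubElement(dv, _d("fcs-dimension"),
                             {_d("name"): div.dimension.channel_ref})
            for v in div.values:
                val = etree.SubElement(dv, _g("value"))
                val.text = _num(_to_data_space(v, div.dimension, strategy))
        for q in node.quadrants:
            qe = etree.SubElement(el, _g("Quadrant"), {_g("id"): f"{gid}.{q.id}",
                                                       _cg("name"): q.id})
            for div_id, k in q.positions:
                etree.SubElement(qe, _g("position"),
                                 {_g("divider_ref"): f"{gid}.{div_id}",
                                  _cg("interval"): str(k)})
    elif isinstance(node, BooleanGate):
        el = etree.SubElement(parent, _g("BooleanGate"), attrs)
        op = etree.SubElement(el, _g(node.operator.lower()))
        for ref, complement in node.operands:
            r = {_g("ref"): id_of[tuple(ref)]}
            if complement:
                r[_g("use-as-complement")] = "true"
            etree.SubElement(op, _g("gateReference"), r)
    else:
        raise NotExpressible(f"gate type {type(node).__name__} cannot be "
                             "expressed in a FlowJo workspace")


def _write_population_tree(parent, strategy: GatingStrategy, base_path, id_of):
    """Nested Population elements mirroring the gate tree below base_path."""
    from .strategy import _QuadrantCell

    children = [p for p in strategy._nodes if p[:-1] == tuple(base_path)]
    if not children:
        return
    subs = etree.SubElement(parent, "Subpopulations")
    for path in children:
        node = strategy._nodes[path]
        pop = etree.SubElement(subs, "Population", {"name": path[-1]})
        if isinstance(node, _QuadrantCell):
            pop.set(_cg("cell"), "1")
        else:
            gate_el = etree.SubElement(pop, "Gate", {_g("id"): path_to_id(path)})
            _write_gate_element(gate_el, node, path, strategy, id_of)
        id_of[path] = path_to_id(path)
        _write_population_tree(pop, strategy, path, id_of)


def write_wsp(session: Session, path=None) -> bytes:
    """Serialize a session as FlowJo-10-shaped workspace XML (deterministic)."""
    root = etree.Element("Workspace", nsmap=NSMAP)
    root.set("version", "20.0")
    root.set("flowJoVersion", FLOWJO_VERSION)

    matrices = etree.SubElement(root, "Matrices")
    seen = set()
    for group in session.groups.values():
        for m in group.template.comp_matrices.values():
            if m.id in seen:
                continue
            seen.add(m.id)
            mel = etree.SubElement(matrices, _t("spilloverMatrix"),
                                   {_t("id"): m.id, "name": m.id})
            for i, det in enumerate(m.detectors):
                row = etree.SubElement(mel, _t("spillover"),
                                       {_d("parameter"): det})
                for j, det2 in enumerate(m.detectors):
                    etree.SubElement(row, _t("coefficient"),
                                     {_d("parameter"): det2,
                                      _t("value"): _num(m.matrix[i, j])})

    sample_list = etree.SubElement(root, "SampleList")
    for sid, smp in session.samples.items():
        sel = etree.SubElement(sample_list, "Sample")
        fname = sid if sid.lower().endswith(".fcs") else f"{sid}.fcs"
        etree.SubElement(sel, "DataSet", {"uri": f"file:{fname}",
                                          "sampleID": sid})
        kws = etree.SubElement(sel, "Keywords")
        for k in ("$TOT", "$PAR", "$DATATYPE"):
            if k in smp.metadata:
                etree.SubElement(kws, "Keyword", {"name": k,
                                                  "value": str(smp.metadata[k])})
        xf = etree.SubElement(sel, "Transformations")
        for group in session.groups.values():
            if sid in group.members:
                for spec in group.template.transforms.values():
                    if spec.kind == "ratio":
                        continue        # not WSP-expressible; gates using it raise
                    _write_wsp_transform(xf, spec)
                break
        etree.SubElement(sel, "SampleNode", {"name": sid, "sampleID": sid})

    groups_el = etree.SubElement(root, "Groups")
    for group in session.groups.values():
        gn = etree.SubElement(groups_el, "GroupNode", {"name": group.name})
        ge = etree.SubElement(gn, "Group", {"name": group.name})
        refs = etree.SubElement(ge, "SampleRefs")
        for sid in group.members:
            etree.SubElement(refs, "SampleRef", {"sampleID": sid})
        id_of = {ROOT: None}
        _write_population_tree(gn, group.template, ROOT, id_of)

    blob = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(blob)
    return blob


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------

def _read_wsp_transform(el) -> TransformSpec:
    tag = etree.QName(el).localname
    tid = el.get(_cg("id")) or tag

    def num(attr, default=None):
        v = el.get(_t(attr))
        if v is None:
            if default is not None:
                return default
            raise SchemaViolation(f"transform {tag!r}: missing attribute {attr}")
        return float(v)

    if tag == "linear":
        return TransformSpec("linear", id=tid, T=num("maxRange"),
                             A=-num("minRange", 0.0))
    if tag == "log":
        return TransformSpec("log", id=tid, T=num("maxRange"), M=num("decades"))
    if tag == "fasinh":
        return TransformSpec("asinh", id=tid, T=num("T"), M=num("M"), A=num("A"))
    if tag in ("logicle", "hyperlog"):
        return TransformSpec(tag, id=tid, T=num("T"), W=num("W"), M=num("M"),
                             A=num("A"))
    if tag == "biex":
        return TransformSpec("flowjo_biex", id=tid, max_value=num("maxRange"),
                             pos_decades=num("pos"), width_basis=num("width"),
                             neg_decades=num("neg"))
    raise UnsupportedElement(f"workspace transform element {tag!r}")


def _read_wsp_dimension(el, strategy, with_bounds: bool) -> Dimension:
    comp = _COMP_IN.get(el.get(_g("compensation-ref"), "uncompensated"),
                        el.get(_g("compensation-ref")))
    tref = el.get(_g("transformation-ref"))
    fcs = el.find(_d("fcs-dimension"))
    if fcs is None:
        raise SchemaViolation("workspace gate dimension without fcs-dimension")
    dim = Dimension(channel_ref=fcs.get(_d("name")), compensation_ref=comp,
                    transform_ref=tref)
    if with_bounds:
        mn = el.get(_g("min"))
        mx = el.get(_g("max"))
        dim = Dimension(
            channel_ref=dim.channel_ref, compensation_ref=comp,
            transform_ref=tref,
            range_min=_to_scale_space(float(mn), dim, strategy) if mn is not None else None,
            range_max=_to_scale_space(float(mx), dim, strategy) if mx is not None else None)
    return dim


def _read_gate_element(el, name, strategy, id_path):
    tag = etree.QName(el).localname
    if tag == "RectangleGate":
        dims = [_read_wsp_dimension(d, strategy, True)
                for d in el.findall(_g("dimension"))]
        return RectangleGate(name, dims)
    if tag == "PolygonGate":
        dims = [_read_wsp_dimension(d, strategy, False)
                for d in el.findall(_g("dimension"))]
        verts = []
        for v in el.findall(_g("vertex")):
            cs = [float(c.get(_d("value"))) for c in v.findall(_g("coordinate"))]
            verts.append([_to_scale_space(cs[0], dims[0], strategy),
                          _to_scale_space(cs[1], dims[1], strategy)])
        return PolygonGate(name, dims, np.array(verts))
    if tag == "EllipsoidGate":
        dims = [_read_wsp_dimension(d, strategy, False)
                for d in el.findall(_g("dimension"))]
        mean = [float(c.get(_d("value")))
                for c in el.find(_g("mean")).findall(_g("coordinate"))]
        cov = [[float(e.get(_d("value"))) for e in row.findall(_g("entry"))]
               for row in el.find(_g("covarianceMatrix")).findall(_g("row"))]
        d2 = float(el.find(_g("distanceSquare")).get(_d("value")))
        return EllipsoidGate(name, dims, np.array(mean), np.array(cov), d2)
    if tag == "QuadrantGate":
        dividers = []
        div_by_ref = {}
        for dv in el.findall(_g("divider")):
            dname = dv.get(_cg("name")) or dv.get(_g("id"))
            dim = _read_wsp_dimension(dv, strategy, False)
            values = tuple(sorted(_to_scale_space(float(v.text), dim, strategy)
                                  for v in dv.findall(_g("value"))))
            d = Divider(dname, dim, values)
            dividers.append(d)
            div_by_ref[dv.get(_g("id"))] = d
        quadrants = []
        for qel in el.findall(_g("Quadrant")):
            qname = qel.get(_cg("name")) or qel.get(_g("id"))
            positions = []
            for pos in qel.findall(_g("position")):
                div = div_by_ref[pos.get(_g("divider_ref"))]
                positions.append((div.id, int(pos.get(_cg("interval")))))
            quadrants.append(Quadrant(qname, tuple(positions)))
        return QuadrantGate(name, dividers, quadrants)
    if tag == "BooleanGate":
        ops = [c for c in el if isinstance(c.tag, str)
               and etree.QName(c).localname in ("and", "or", "not")]
        if len(ops) != 1:
            raise SchemaViolation(f"boolean gate {name!r}: needs one and/or/not")
        operands = []
        for ref_el in ops[0].findall(_g("gateReference")):
            ref = ref_el.get(_g("ref"))
            if ref not in id_path:
                raise SchemaViolation(f"boolean gate {name!r}: reference {ref!r} "
                                      "undefined at this point")
            operands.append((id_path[ref],
                             ref_el.get(_g("use-as-complement")) == "true"))
        return BooleanGate(name, etree.QName(ops[0]).localname.upper(), operands)
    raise UnsupportedElement(f"workspace gate element {tag!r}")


def _read_population_tree(parent_el, strategy, base_path, id_path, warnings):
    for subs in parent_el.findall("Subpopulations"):
        for pop in subs.findall("Population"):
            name = pop.get("name")
            if pop.get(_cg("cell")) == "1":
                path = tuple(base_path) + (name,)
            else:
                gate_holder = pop.find("Gate")
                if gate_holder is None:
                    warnings.append(f"population {name!r} has no gate; skipped")
                    continue
                gate_els = [c for c in gate_holder if isinstance(c.tag, str)]
                if len(gate_els) != 1:
                    raise SchemaViolation(f"population {name!r}: Gate must hold "
                                          "exactly one gate element")
                gate = _read_gate_element(gate_els[0], name, strategy, id_path)
                path = strategy.add_gate(gate, tuple(base_path))
                id_path[gate_holder.get(_g("id")) or path_to_id(path)] = path
                if isinstance(gate, QuadrantGate):
                    for q in gate.quadrants:
                        id_path[f"{path_to_id(path)}.{q.id}"] = path + (q.id,)
            _read_population_tree(pop, strategy, path, id_path, warnings)


def read_wsp(source, fcs_directory) -> tuple[Session, list[str]]:
    """Read a FlowJo 10 workspace; returns ``(session, warnings)``.

    FCS files are located by the basename of each sample's DataSet uri
    inside ``fcs_directory`` (URI directory components are not trusted).
    """
    if isinstance(source, (bytes, bytearray)):
        root = etree.fromstring(bytes(source))
    else:
        root = etree.parse(source).getroot()
    if root.tag != "Workspace":
        raise SchemaViolation(f"not a FlowJo workspace (root {root.tag!r})")
    fj = root.get("flowJoVersion") or root.get("version") or "0"
    try:
        major = int(str(fj).split(".")[0])
    except ValueError:
        major = 0
    if major < 10:
        raise UnsupportedWorkspaceVersion(
            f"workspace version {fj!r} predates FlowJo 10")

    warnings: list[str] = []
    session = Session()

    matrices: dict[str, SpilloverMatrix] = {}
    mats_el = root.find("Matrices")
    if mats_el is not None:
        for mel in mats_el.findall(_t("spilloverMatrix")):
            mid = mel.get(_t("id")) or mel.get("name") or "comp"
            rows = mel.findall(_t("spillover"))
            detectors = [r.get(_d("parameter")) for r in rows]
            mat = np.zeros((len(rows), len(rows)))
            for i, r in enumerate(rows):
                coeffs = {c.get(_d("parameter")): float(c.get(_t("value")))
                          for c in r.findall(_t("coefficient"))}
                for j, det in enumerate(detectors):
                    mat[i, j] = coeffs.get(det, 1.0 if i == j else 0.0)
            matrices[mid] = SpilloverMatrix(detectors, mat, id=mid)

    sample_transforms: dict[str, list[TransformSpec]] = {}
    sl = root.find("SampleList")
    if sl is not None:
        for sel in sl.findall("Sample"):
            ds = sel.find("DataSet")
            if ds is None:
                raise SchemaViolation("Sample entry without DataSet")
            uri = ds.get("uri", "")
            base = os.path.basename(unquote(urlparse(uri).path or uri))
            node = sel.find("SampleNode")
            sid = (node.get("name") if node is not None else None) or \
                ds.get("sampleID") or os.path.splitext(base)[0]
            fpath = os.path.join(fcs_directory, base)
            if not os.path.exists(fpath):
                raise SampleFileMissing(f"FCS file {base!r} not found in "
                                        f"{fcs_directory}")
            if node is not None and node.find("Subpopulations") is not None:
                raise UnsupportedElement(
                    f"sample {sid!r} carries per-sample gate modifications; "
                    "only group templates are supported")
            smp = fcs_io.read_fcs(fpath, sample_id=sid)
            session.add_samples(smp)
            xf = sel.find("Transformations")
            specs = []
            if xf is not None:
                for tel in xf:
                    if not isinstance(tel.tag, str):
                        continue
                    specs.append(_read_wsp_transform(tel))
            sample_transforms[sid] = specs

    groups_el = root.find("Groups")
    if groups_el is not None:
        for gn in groups_el.findall("GroupNode"):
            gname = gn.get("name")
            strategy = GatingStrategy()
            for m in matrices.values():
                strategy.add_comp_matrix(m)
            members = []
            ge = gn.find("Group")
            if ge is not None:
                refs = ge.find("SampleRefs")
                if refs is not None:
                    members = [r.get("sampleID") for r in refs.findall("SampleRef")]
            for sid in members:
                for spec in sample_transforms.get(sid, []):
                    if spec.id not in strategy.transforms:
                        strategy.add_transform(spec)
            _read_population_tree(gn, strategy, ROOT, {}, warnings)
            grp = session.create_group(gname, template=strategy)
            for sid in members:
                if sid not in session.samples:
                    raise SchemaViolation(f"group {gname!r} references unknown "
                                          f"sample {sid!r}")
                grp.members.append(sid)

    for el in root:
        if el.tag not in ("Matrices", "SampleList", "Groups") \
                and isinstance(el.tag, str):
            warnings.append(f"workspace element {el.tag!r} not understood; ignored")
    return session, warnings
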