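"""Gating-ML 2.0 XML import/export for gating strategies.

Covers the gate elements RectangleGate (incl. 1-D ranges), PolygonGate,
EllipsoidGate, QuadrantGate and BooleanGate, the transform elements flin,
flog, fasinh, logicle, hyperlog and fratio, and document-defined
spectrumMatrix compensation.  Unsupported corner elements raise
:class:`UnsupportedElement` rather than being skipped silently.

Gate ids on write are sanitized path strings; a sidecar attribute in a
private namespace keeps the display name so read(write(s)) restores the
original gate names.  Output is deterministic byte-for-byte for a fixed
strategy.
"""

from __future__ import annotations

import re

import numpy as np
from lxml import etree

from .compensation import SpilloverMatrix
from .exceptions import (
    NotExpressible,
    SchemaViolation,
    UnresolvedId,
    UnsupportedElement,
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
from .strategy import ROOT, GatingStrategy
from .transforms import TransformSpec

NS_G = "http://www.isac-net.org/std/Gating-ML/v2.0/gating"
NS_T = "http://www.isac-net.org/std/Gating-ML/v2.0/transformations"
NS_D = "http://www.isac-net.org/std/Gating-ML/v2.0/datatypes"
NS_X = "urn:cytogate-sidecar"          # private: display names

NSMAP = {"gating": NS_G, "transforms": NS_T, "data-type": NS_D, "cg": NS_X}


def _g(tag):
    return f"{{{NS_G}}}{tag}"


def _t(tag):
    return f"{{{NS_T}}}{tag}"


def _d(tag):
    return f"{{{NS_D}}}{tag}"


def _num(v: float) -> str:
    # shortest repr that round-trips the float exactly
    return repr(float(v))


def _sanitize(text: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_.-]", "_", text)
    return out if out and not out[0].isdigit() else "_" + out


def path_to_id(path) -> str:
    return _sanitize(".".join(path[1:]))      # drop the implicit "root"


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def _write_transform(parent, spec: TransformSpec):
    el = etree.SubElement(parent, _t("transformation"))
    el.set(_t("id"), spec.id)
    if spec.kind == "linear":
        etree.SubElement(el, _t("flin"),
                         {_t("T"): _num(spec.T), _t("A"): _num(spec.A)})
    elif spec.kind == "log":
        etree.SubElement(el, _t("flog"),
                         {_t("T"): _num(spec.T), _t("M"): _num(spec.M)})
    elif spec.kind == "asinh":
        etree.SubElement(el, _t("fasinh"),
                         {_t("T"): _num(spec.T), _t("M"): _num(spec.M),
                          _t("A"): _num(spec.A)})
    elif spec.kind in ("logicle", "hyperlog"):
        etree.SubElement(el, _t(spec.kind),
                         {_t("T"): _num(spec.T), _t("W"): _num(spec.W),
                          _t("M"): _num(spec.M), _t("A"): _num(spec.A)})
    elif spec.kind == "ratio":
        fr = etree.SubElement(el, _t("fratio"),
                              {_t("A"): _num(spec.A_r), _t("B"): _num(spec.B_r),
                               _t("C"): _num(spec.C_r)})
        for ch in (spec.num_channel, spec.den_channel):
            etree.SubElement(fr, _d("fcs-dimension"), {_d("name"): ch})
    else:
        raise NotExpressible(
            f"transform {spec.id!r} of kind {spec.kind!r} cannot be expressed "
            "in Gating-ML 2.0")


def _write_matrix(parent, m: SpilloverMatrix):
    el = etree.SubElement(parent, _t("spectrumMatrix"))
    el.set(_t("id"), m.id)
    fl = etree.SubElement(el, _t("fluorochromes"))
    de = etree.SubElement(el, _t("detectors"))
    for d in m.detectors:
        etree.SubElement(fl, _d("fcs-dimension"), {_d("name"): d})
        etree.SubElement(de, _d("fcs-dimension"), {_d("name"): d})
    for row in m.matrix:
        sp = etree.SubElement(el, _t("spectrum"))
        for v in row:
            etree.SubElement(sp, _t("coefficient"), {_t("value"): _num(v)})


_COMP_OUT = {"none": "uncompensated", "fcs": "FCS", None: "uncompensated",
             "": "uncompensated"}
_COMP_IN = {"uncompensated": "none", "FCS": "fcs"}


def _write_dimension(parent, dim: Dimension, strategy: GatingStrategy,
                     with_bounds: bool):
    attrs = {_g("compensation-ref"): _COMP_OUT.get(dim.compensation_ref,
                                                   dim.compensation_ref)}
    if dim.transform_ref:
        attrs[_g("transformation-ref")] = dim.transform_ref
    if with_bounds:
        if dim.range_min is not None:
            attrs[_g("min")] = _num(dim.range_min)
        if dim.range_max is not None:
            attrs[_g("max")] = _num(dim.range_max)
    el = etree.SubElement(parent, _g("dimension"), attrs)
    tspec = strategy.transforms.get(dim.channel_ref)
    if tspec is not None and tspec.kind == "ratio":
        etree.SubElement(el, _d("new-dimension"),
                         {_d("transformation-ref"): dim.channel_ref})
    else:
        etree.SubElement(el, _d("fcs-dimension"), {_d("name"): dim.channel_ref})


def write_gatingml(strategy: GatingStrategy, path=None) -> bytes:
    """Serialize a strategy as Gating-ML 2.0 XML bytes (optionally to a file)."""
    root = etree.Element(_g("Gating-ML"), nsmap=NSMAP)
    for spec in strategy.transforms.values():
        _write_transform(root, spec)
    for m in strategy.comp_matrices.values():
        _write_matrix(root, m)

    id_of = {ROOT: None}
    from .strategy import _QuadrantCell

    for gpath, node in strategy._nodes.items():
        gid = path_to_id(gpath)
        id_of[gpath] = gid
        if isinstance(node, _QuadrantCell):
            continue                       # cells serialize inside their gate
        parent_id = id_of[gpath[:-1]]
        attrs = {_g("id"): gid}
        if parent_id is not None:
            attrs[_g("parent_id")] = parent_id
        attrs[f"{{{NS_X}}}name"] = node.name

        if isinstance(node, RectangleGate):
            el = etree.SubElement(root, _g("RectangleGate"), attrs)
            for dim in node.dimensions:
                _write_dimension(el, dim, strategy, with_bounds=True)
        elif isinstance(node, PolygonGate):
            el = etree.SubElement(root, _g("PolygonGate"), attrs)
            for dim in node.dimensions:
                _write_dimension(el, dim, strategy, with_bounds=False)
            for x, y in node.vertices:
                v = etree.SubElement(el, _g("vertex"))
                etree.SubElement(v, _g("coordinate"), {_d("value"): _num(x)})
                etree.SubElement(v, _g("coordinate"), {_d("value"): _num(y)})
        elif isinstance(node, EllipsoidGate):
            el = etree.SubElement(root, _g("EllipsoidGate"), attrs)
            for dim in node.dimensions:
                _write_dimension(el, dim, strategy, with_bounds=False)
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
            el = etree.SubElement(root, _g("QuadrantGate"), attrs)
            for div in node.dividers:
                dv = etree.SubElement(el, _g("divider"))
                dv.set(_g("id"), f"{gid}.{_sanitize(div.id)}")
                dv.set(f"{{{NS_X}}}name", div.id)
                dv.set(_g("compensation-ref"),
                       _COMP_OUT.get(div.dimension.compensation_ref,
                                     div.dimension.compensation_ref))
                if div.dimension.transform_ref:
                    dv.set(_g("transformation-ref"), div.dimension.transform_ref)
                etree.SubElement(dv, _d("fcs-dimension"),
                                 {_d("name"): div.dimension.channel_ref})
                for v in div.values:
                    val = etree.SubElement(dv, _g("value"))
                    val.text = _num(v)
            for q in node.quadrants:
                qe = etree.SubElement(el, _g("Quadrant"))
                qe.set(_g("id"), f"{gid}.{_sanitize(q.id)}")
                qe.set(f"{{{NS_X}}}name", q.id)
                for div_id, k in q.positions:
                    div = next(d for d in node.dividers if d.id == div_id)
                    vals = div.values
                    if k == 0:
                        loc = vals[0] - 1.0
                    elif k == len(vals):
                        loc = vals[-1] + 1.0
                    else:
                        loc = 0.5 * (vals[k - 1] + vals[k])
                    etree.SubElement(qe, _g("position"),
                                     {_g("divider_ref"): f"{gid}.{_sanitize(div_id)}",
                                      _g("location"): _num(loc)})
        elif isinstance(node, BooleanGate):
            el = etree.SubElement(root, _g("BooleanGate"), attrs)
            op = etree.SubElement(el, _g(node.operator.lower()))
            for ref, complement in node.operands:
                r = {_g("ref"): id_of[tuple(ref)]}
                if complement:
                    r[_g("use-as-complement")] = "true"
                etree.SubElement(op, _g("gateReference"), r)
        else:                              # pragma: no cover
            raise NotExpressible(f"gate type {type(node).__name__} at "
                                 f"{'/'.join(gpath)}")

    blob = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(blob)
    return blob


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def _read_transform(el) -> TransformSpec:
    tid = el.get(_t("id"))
    if tid is None:
        raise SchemaViolation("transformation without transforms:id")
    children = [c for c in el if isinstance(c.tag, str)]
    if len(children) != 1:
        raise SchemaViolation(f"transformation {tid!r} must have one child element")
    c = children[0]
    tag = etree.QName(c).localname

    def num(attr):
        v = c.get(_t(attr))
        if v is None:
            raise SchemaViolation(f"transformation {tid!r}: missing {attr}")
        return float(v)

    if tag == "flin":
        return TransformSpec("linear", id=tid, T=num("T"), A=num("A"))
    if tag == "flog":
        return TransformSpec("log", id=tid, T=num("T"), M=num("M"))
    if tag == "fasinh":
        return TransformSpec("asinh", id=tid, T=num("T"), M=num("M"), A=num("A"))
    if tag in ("logicle", "hyperlog"):
        return TransformSpec(tag, id=tid, T=num("T"), W=num("W"),
                             M=num("M"), A=num("A"))
    if tag == "fratio":
        dims = c.findall(_d("fcs-dimension"))
        if len(dims) != 2:
            raise SchemaViolation(f"fratio {tid!r} needs two fcs-dimension children")
        return TransformSpec("ratio", id=tid, A_r=num("A"), B_r=num("B"),
                             C_r=num("C"),
                             num_channel=dims[0].get(_d("name")),
                             den_channel=dims[1].get(_d("name")))
    raise UnsupportedElement(f"transformation child element {tag!r}")


def _read_matrix(el) -> SpilloverMatrix:
    mid = el.get(_t("id")) or "spectrum"
    det_el = el.find(_t("detectors"))
    if det_el is None:
        raise SchemaViolation(f"spectrumMatrix {mid!r} lacks detectors")
    detectors = [d.get(_d("name")) for d in det_el.findall(_d("fcs-dimension"))]
    rows = []
    for sp in el.findall(_t("spectrum")):
        rows.append([float(co.get(_t("value")))
                     for co in sp.findall(_t("coefficient"))])
    return SpilloverMatrix(detectors, np.array(rows), id=mid)


def _read_dimension(el, with_bounds: bool) -> Dimension:
    comp = el.get(_g("compensation-ref"), "uncompensated")
    comp = _COMP_IN.get(comp, comp)
    tref = el.get(_g("transformation-ref"))
    rng_min = el.get(_g("min"))
    rng_max = el.get(_g("max"))
    fcs = el.find(_d("fcs-dimension"))
    new = el.find(_d("new-dimension"))
    if fcs is not None:
        channel = fcs.get(_d("name"))
    elif new is not None:
        channel = new.get(_d("transformation-ref"))
        if channel is None:
            raise SchemaViolation("new-dimension without transformation-ref")
    else:
        raise UnsupportedElement("dimension without fcs-dimension/new-dimension "
                                 "content")
    return Dimension(channel_ref=channel, compensation_ref=comp,
                     transform_ref=tref,
                     range_min=float(rng_min) if (with_bounds and rng_min is not None) else None,
                     range_max=float(rng_max) if (with_bounds and rng_max is not None) else None)


_GATE_TAGS = ("RectangleGate", "PolygonGate", "EllipsoidGate", "QuadrantGate",
              "BooleanGate")


def read_gatingml(source) -> GatingStrategy:
    """Parse Gating-ML 2.0 XML (bytes, path or file-like) into a strategy."""
    if isinstance(source, (bytes, bytearray)):
        root = etree.fromstring(bytes(source))
    else:
        root = etree.parse(source).getroot()
    if etree.QName(root).namespace != NS_G:
        raise SchemaViolation(f"root element not in the Gating-ML gating "
                              f"namespace: {root.tag}")

    strategy = GatingStrategy()
    raw_gates = []                    # (gid, parent_gid, element)
    for el in root:
        if not isinstance(el.tag, str):
            continue
        qn = etree.QName(el)
        if qn.namespace == NS_T:
            if qn.localname == "transformation":
                strategy.add_transform(_read_transform(el))
            elif qn.localname == "spectrumMatrix":
                strategy.add_comp_matrix(_read_matrix(el))
            else:
                raise UnsupportedElement(f"transforms element {qn.localname!r}")
        elif qn.namespace == NS_G:
            if qn.localname not in _GATE_TAGS:
                raise UnsupportedElement(f"gating element {qn.localname!r}")
            gid = el.get(_g("id"))
            if gid is None:
                raise SchemaViolation(f"{qn.localname} without gating:id")
            raw_gates.append((gid, el.get(_g("parent_id")), el))
        else:
            raise UnsupportedElement(f"element {el.tag!r} outside the "
                                     "Gating-ML namespaces")

    ids = {gid for gid, _p, _e in raw_gates}
    for _gid, _p, el in raw_gates:
        # quadrant cell ids are legal parents / boolean operands too
        for qel in el.findall(_g("Quadrant")):
            qid = qel.get(_g("id"))
            if qid:
                ids.add(qid)
    id_path: dict[str, tuple] = {}
    pending = list(raw_gates)
    guard = 0
    while pending:
        guard += 1
        if guard > len(raw_gates) + 2:
            unresolved = sorted(p for _g2, p, _e in pending if p is not None)
            raise UnresolvedId(f"unresolvable or cyclic parent ids: {unresolved}")
        still = []
        for gid, parent, el in pending:
            if gid in id_path:
                raise SchemaViolation(f"duplicate gate id {gid!r}")
            if parent is None:
                parent_path = ROOT
            elif parent in id_path:
                parent_path = id_path[parent]
            elif parent in ids:
                still.append((gid, parent, el))
                continue
            else:
                raise UnresolvedId(f"gate {gid!r}: dangling parent id {parent!r}")
            gate = _build_gate(el, gid, id_path)
            path = strategy.add_gate(gate, parent_path)
            id_path[gid] = path
            if isinstance(gate, QuadrantGate):
                # quadrant cells are addressable as parents / boolean operands
                for qel in el.findall(_g("Quadrant")):
                    qid = qel.get(_g("id"))
                    qname = qel.get(f"{{{NS_X}}}name") or qid
                    id_path[qid] = path + (qname,)
        pending = still
    return strategy


def _build_gate(el, gid: str, id_path: dict):
    tag = etree.QName(el).localname
    name = el.get(f"{{{NS_X}}}name") or gid.split(".")[-1]

    if tag == "RectangleGate":
        dims = [_read_dimension(d, with_bounds=True)
                for d in el.findall(_g("dimension"))]
        return RectangleGate(name, dims)
    if tag == "PolygonGate":
        dims = [_read_dimension(d, with_bounds=False)
                for d in el.findall(_g("dimension"))]
        verts = []
        for v in el.findall(_g("vertex")):
            cs = [float(c.get(_d("value"))) for c in v.findall(_g("coordinate"))]
            if len(cs) != 2:
                raise SchemaViolation(f"polygon {gid!r}: vertex needs 2 coordinates")
            verts.append(cs)
        return PolygonGate(name, dims, np.array(verts))
    if tag == "EllipsoidGate":
        dims = [_read_dimension(d, with_bounds=False)
                for d in el.findall(_g("dimension"))]
        mean_el = el.find(_g("mean"))
        cov_el = el.find(_g("covarianceMatrix"))
        d2_el = el.find(_g("distanceSquare"))
        if mean_el is None or cov_el is None or d2_el is None:
            raise SchemaViolation(f"ellipsoid {gid!r}: mean/covarianceMatrix/"
                                  "distanceSquare required")
        mean = [float(c.get(_d("value")))
                for c in mean_el.findall(_g("coordinate"))]
        cov = [[float(e.get(_d("value"))) for e in row.findall(_g("entry"))]
               for row in cov_el.findall(_g("row"))]
        return EllipsoidGate(name, dims, np.array(mean), np.array(cov),
                             float(d2_el.get(_d("value"))))
    if tag == "QuadrantGate":
        dividers = []
        for dv in el.findall(_g("divider")):
            dname = dv.get(f"{{{NS_X}}}name") or dv.get(_g("id"))
            dim = _read_dimension(dv, with_bounds=False)
            values = tuple(float(v.text) for v in dv.findall(_g("value")))
            dividers.append(Divider(dname, dim, values))
        div_by_ref = {}
        for dv, d in zip(el.findall(_g("divider")), dividers):
            div_by_ref[dv.get(_g("id"))] = d
        quadrants = []
        for qel in el.findall(_g("Quadrant")):
            qid = qel.get(_g("id"))
            qname = qel.get(f"{{{NS_X}}}name") or qid
            positions = []
            for pos in qel.findall(_g("position")):
                ref = pos.get(_g("divider_ref"))
                if ref not in div_by_ref:
                    raise UnresolvedId(f"quadrant {qid!r}: unknown divider ref "
                                       f"{ref!r}")
                div = div_by_ref[ref]
                loc = float(pos.get(_g("location")))
                k = int(np.searchsorted(np.asarray(div.values), loc, side="right"))
                positions.append((div.id, k))
            quadrants.append(Quadrant(qname, tuple(positions)))
        return QuadrantGate(name, dividers, quadrants)
    if tag == "BooleanGate":
        ops = [c for c in el if isinstance(c.tag, str)
               and etree.QName(c).localname in ("and", "or", "not")]
        if len(ops) != 1:
            raise SchemaViolation(f"boolean {gid!r}: needs one and/or/not child")
        op = ops[0]
        operands = []
        for ref_el in op.findall(_g("gateReference")):
            ref = ref_el.get(_g("ref"))
            if ref not in id_path:
                raise UnresolvedId(f"boolean {gid!r}: reference {ref!r} undefined "
                                   "(forward references are rejected)")
            complement = ref_el.get(_g("use-as-complement")) == "true"
            operands.append((id_path[ref], complement))
        return BooleanGate(name, etree.QName(op).localname.upper(), operands)
    raise UnsupportedElement(f"gate element {tag!r}")      # pragma: no cover
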