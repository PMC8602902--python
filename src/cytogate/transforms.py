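"""Display transforms for cytometry event data.

Seven transform families are supported, following the Gating-ML 2.0
parameterization: ``linear``, ``log``, ``asinh``, ``ratio``, ``logicle``,
``hyperlog`` and ``flowjo_biex``.

The logicle scale is the inverse of a biexponential function

    B(y) = a*exp(b*y) - c*exp(-d*y) - f        for y >= x1,

extended to y < x1 by odd reflection about the point (x1, 0), where x1 is
the scale position of data value zero.  The parameters (a, b, c, d, f) are
fixed by the user-facing quadruple (T, W, M, A): T is the top-of-scale data
value (maps to scale 1), M the total number of display decades, W the width
of the quasi-linear region around zero in decades, and A the number of
additional negative display decades.  B has no closed-form inverse, so the
forward transform is computed per value by a safeguarded Newton iteration.

The hyperlog scale is defined the same way with the generating function

    EH(y) = a*exp(b*y) + c*y - f               for y >= x1,

again reflected odd about (x1, 0).

The FlowJo biexponential is defined operationally: the biexponential family
above, driven by FlowJo's (max_value, pos_decades, width_basis,
neg_decades) parameters, is tabulated on a dense node grid and evaluated by
linear interpolation; the inverse is the same table read backwards.

All forward transforms are strictly increasing on their domain and map the
top-of-scale value T to 1 (for A = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .exceptions import (
    InvalidParams,
    NonConvergence,
    NotInvertible,
    UnknownChannel,
)

LN10 = math.log(10.0)

KINDS = ("linear", "log", "asinh", "ratio", "logicle", "hyperlog", "flowjo_biex")

#: number of nodes in the FlowJo biexponential lookup table
BIEX_LUT_NODES = 8192

#: root-finder iteration cap for logicle / hyperlog
MAX_ITER = 200


@dataclass(frozen=True)
class TransformSpec:
    """Tagged parameter set naming one transform family.

    Only the fields relevant to ``kind`` are used; validation happens in
    :func:`validate_spec`, which every apply/invert entry point calls.
    """

    kind: str
    id: str = ""
    T: float | None = None
    W: float | None = None
    M: float | None = None
    A: float | None = None
    # ratio parameters
    A_r: float | None = None
    B_r: float | None = None
    C_r: float | None = None
    num_channel: str | None = None
    den_channel: str | None = None
    # flowjo_biex parameters
    max_value: float | None = None
    pos_decades: float | None = None
    width_basis: float | None = None
    neg_decades: float | None = None

    def with_id(self, new_id: str) -> "TransformSpec":
        return replace(self, id=new_id)


def linear(T: float, A: float = 0.0, id: str = "") -> TransformSpec:
    return TransformSpec("linear", id=id, T=T, A=A)


def log(T: float, M: float, id: str = "") -> TransformSpec:
    return TransformSpec("log", id=id, T=T, M=M)


def asinh(T: float, M: float, A: float = 0.0, id: str = "") -> TransformSpec:
    return TransformSpec("asinh", id=id, T=T, M=M, A=A)


def logicle(T: float, W: float, M: float, A: float = 0.0, id: str = "") -> TransformSpec:
    return TransformSpec("logicle", id=id, T=T, W=W, M=M, A=A)


def hyperlog(T: float, W: float, M: float, A: float = 0.0, id: str = "") -> TransformSpec:
    return TransformSpec("hyperlog", id=id, T=T, W=W, M=M, A=A)


def ratio(num_channel: str, den_channel: str, A: float = 1.0, B: float = 0.0,
          C: float = 0.0, id: str = "") -> TransformSpec:
    return TransformSpec("ratio", id=id, A_r=A, B_r=B, C_r=C,
                         num_channel=num_channel, den_channel=den_channel)


def flowjo_biex(max_value: float = 262144.0, pos_decades: float = 4.418540,
                width_basis: float = -10.0, neg_decades: float = 0.0,
                id: str = "") -> TransformSpec:
    return TransformSpec("flowjo_biex", id=id, max_value=max_value,
                         pos_decades=pos_decades, width_basis=width_basis,
                         neg_decades=neg_decades)


def validate_spec(spec: TransformSpec) -> None:
    """Raise :class:`InvalidParams` on any parameter-bound violation.

    Bounds follow Gating-ML 2.0: logicle requires 0 <= W <= M/2 and
    -W <= A <= M - 2W; hyperlog additionally requires W > 0.
    """
    k = spec.kind
    if k not in KINDS:
        raise InvalidParams(f"unknown transform kind {k!r}")
    if k == "linear":
        if spec.T is None or spec.T <= 0 or spec.A is None or spec.A < 0:
            raise InvalidParams(f"linear requires T > 0 and A >= 0, got T={spec.T}, A={spec.A}")
    elif k == "log":
        if spec.T is None or spec.T <= 0 or spec.M is None or spec.M <= 0:
            raise InvalidParams(f"log requires T > 0 and M > 0, got T={spec.T}, M={spec.M}")
    elif k == "asinh":
        if (spec.T is None or spec.T <= 0 or spec.M is None or spec.M <= 0
                or spec.A is None or spec.A < 0):
            raise InvalidParams(f"asinh requires T > 0, M > 0, A >= 0, got "
                                f"T={spec.T}, M={spec.M}, A={spec.A}")
    elif k in ("logicle", "hyperlog"):
        T, W, M, A = spec.T, spec.W, spec.M, spec.A
        if T is None or W is None or M is None or A is None:
            raise InvalidParams(f"{k} requires T, W, M, A")
        if T <= 0 or M <= 0:
            raise InvalidParams(f"{k} requires T > 0 and M > 0")
        if not (0 <= W <= M / 2):
            raise InvalidParams(f"{k} requires 0 <= W <= M/2, got W={W}, M={M}")
        if k == "hyperlog" and W == 0:
            raise InvalidParams("hyperlog requires W > 0")
        if not (-W <= A <= M - 2 * W):
            raise InvalidParams(f"{k} requires -W <= A <= M - 2W, got W={W}, M={M}, A={A}")
    elif k == "ratio":
        if spec.A_r is None or spec.B_r is None or spec.C_r is None:
            raise InvalidParams("ratio requires A, B, C coefficients")
        if not spec.num_channel or not spec.den_channel:
            raise InvalidParams("ratio requires numerator and denominator channel names")
    elif k == "flowjo_biex":
        if spec.max_value is None or spec.max_value <= 0:
            raise InvalidParams("flowjo_biex requires max_value > 0")
        if spec.pos_decades is None or spec.pos_decades <= 0:
            raise InvalidParams("flowjo_biex requires pos_decades > 0")
        if spec.width_basis is None or spec.width_basis > 0:
            raise InvalidParams("flowjo_biex requires width_basis <= 0")
        if spec.neg_decades is None or spec.neg_decades < 0:
            raise InvalidParams("flowjo_biex requires neg_decades >= 0")


# --------------------------------------------------------------------------
# Biexponential machinery (shared by logicle, hyperlog, flowjo_biex)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _BiexParams:
    a: float
    b: float
    c: float
    d: float
    f: float
    x1: float
    T: float


def _solve_d(b: float, w: float) -> float:
    """Solve 2*(ln d - ln b) + w*(b + d) = 0 for d in (0, b]."""
    if w == 0:
        return b
    fn = lambda d: 2.0 * (math.log(d) - math.log(b)) + w * (b + d)
    # fn(b) = w*2b > 0; fn -> -inf as d -> 0+
    return brentq(fn, 1e-300, b, xtol=1e-300, rtol=8.9e-16, maxiter=200)


def _logicle_params(T: float, W: float, M: float, A: float) -> _BiexParams:
    w = W / (M + A)
    x2 = A / (M + A)
    x1 = x2 + w
    x0 = x2 + 2.0 * w
    b = (M + A) * LN10
    d = _solve_d(b, w)
    c_a = math.exp(x0 * (b + d))
    mf_a = math.exp(b * x1) - c_a * math.exp(-d * x1)
    a = T / ((math.exp(b) - c_a * math.exp(-d)) - mf_a)
    c = c_a * a
    f = mf_a * a
    return _BiexParams(a=a, b=b, c=c, d=d, f=f, x1=x1, T=T)


def _biex_value(p: _BiexParams, y):
    """Evaluate the reflected biexponential B(y) (the logicle inverse)."""
    y = np.asarray(y, dtype=float)
    u = p.x1 + np.abs(y - p.x1)
    mag = p.a * np.exp(p.b * u) - p.c * np.exp(-p.d * u) - p.f
    return np.where(y >= p.x1, mag, -mag)


def _biex_deriv(p: _BiexParams, y):
    y = np.asarray(y, dtype=float)
    u = p.x1 + np.abs(y - p.x1)
    return p.a * p.b * np.exp(p.b * u) + p.c * p.d * np.exp(-p.d * u)


@dataclass(frozen=True)
class _HyperlogParams:
    a: float
    b: float
    c: float
    f: float
    x1: float
    T: float


def _hyperlog_params(T: float, W: float, M: float, A: float) -> _HyperlogParams:
    w = W / (M + A)
    x2 = A / (M + A)
    x1 = x2 + w
    x0 = x2 + 2.0 * w
    b = (M + A) * LN10
    e0 = math.exp(b * x0)
    c_a = e0 / w
    f_a = math.exp(b * x1) + c_a * x1
    a = T / (math.exp(b) + c_a - f_a)
    c = c_a * a
    f = f_a * a
    return _HyperlogParams(a=a, b=b, c=c, f=f, x1=x1, T=T)


def _eh_value(p: _HyperlogParams, y):
    """Evaluate the reflected hyperlog generator EH(y)."""
    y = np.asarray(y, dtype=float)
    u = p.x1 + np.abs(y - p.x1)
    mag = p.a * np.exp(p.b * u) + p.c * u - p.f
    return np.where(y >= p.x1, mag, -mag)


def _eh_deriv(p: _HyperlogParams, y):
    y = np.asarray(y, dtype=float)
    u = p.x1 + np.abs(y - p.x1)
    return p.a * p.b * np.exp(p.b * u) + p.c


def _invert_monotone(values, x1: float, T: float, func, deriv):
    """Solve func(y) = v per element by safeguarded vectorized Newton.

    ``func`` must be strictly increasing, odd about (x1, 0), with
    func(x1) = 0.  Solutions for negative targets use the odd symmetry:
    y(-v) = 2*x1 - y(v).
    """
    v = np.asarray(values, dtype=float)
    scalar = v.ndim == 0
    v = np.atleast_1d(v).astype(float)
    out = np.full(v.shape, np.nan)
    finite = np.isfinite(v)
    mag = np.abs(v[finite])
    sgn = np.sign(v[finite])

    # bracket on the upper branch: y in [x1, hi]
    lo = np.full(mag.shape, x1)
    hi = np.full(mag.shape, 1.0)
    for _ in range(200):
        need = func(hi) < mag
        if not need.any():
            break
        hi = np.where(need, hi + 0.5, hi)
    else:
        raise NonConvergence("could not bracket transform root")

    y = 0.5 * (lo + hi)
    tol = max(T, 1.0) * 1e-13
    converged = np.zeros(mag.shape, dtype=bool)
    for _ in range(MAX_ITER):
        fy = func(y) - mag
        converged = np.abs(fy) <= tol
        if converged.all():
            break
        lo = np.where(fy < 0, y, lo)
        hi = np.where(fy > 0, y, hi)
        step = fy / deriv(y)
        y_new = y - step
        # fall back to bisection when Newton leaves the bracket
        bad = (y_new <= lo) | (y_new >= hi) | ~np.isfinite(y_new)
        y = np.where(bad, 0.5 * (lo + hi), y_new)
    else:
        if not converged.all():
            raise NonConvergence(
                f"transform root finder failed for {int((~converged).sum())} values")

    res = np.where(sgn >= 0, y, 2.0 * x1 - y)
    out[finite] = res
    out[~finite] = np.where(np.asarray(v[~finite]) > 0, np.inf, -np.inf)
    return out[0] if scalar else out


# --------------------------------------------------------------------------
# Public apply/invert operations
# --------------------------------------------------------------------------

def apply_closed_form(values, spec: TransformSpec):
    """Apply a linear, log or asinh transform.

    log of non-positive values yields ``-inf`` rather than raising, so
    whole-matrix transforms never abort; callers that need to trap these
    should mask on finiteness.
    """
    validate_spec(spec)
    x = np.asarray(values, dtype=float)
    if spec.kind == "linear":
        return (x + spec.A) / (spec.T + spec.A)
    if spec.kind == "log":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (1.0 / spec.M) * np.log10(x / spec.T) + 1.0
        return np.where(x > 0, out, -np.inf)
    if spec.kind == "asinh":
        m = spec.M * LN10
        return (np.arcsinh(x * math.sinh(m) / spec.T) + spec.A * LN10) / ((spec.M + spec.A) * LN10)
    raise InvalidParams(f"apply_closed_form cannot handle kind {spec.kind!r}")


def apply_logicle(values, spec: TransformSpec):
    """Logicle transform: per-value root of the biexponential B(y) = x."""
    validate_spec(spec)
    if spec.kind != "logicle":
        raise InvalidParams(f"expected logicle spec, got {spec.kind!r}")
    p = _logicle_params(spec.T, spec.W, spec.M, spec.A)
    return _invert_monotone(values, p.x1, p.T,
                            lambda y: _biex_value(p, y),
                            lambda y: _biex_deriv(p, y))


def apply_hyperlog(values, spec: TransformSpec):
    """Hyperlog transform: per-value root of EH(y) = x."""
    validate_spec(spec)
    if spec.kind != "hyperlog":
        raise InvalidParams(f"expected hyperlog spec, got {spec.kind!r}")
    p = _hyperlog_params(spec.T, spec.W, spec.M, spec.A)
    return _invert_monotone(values, p.x1, p.T,
                            lambda y: _eh_value(p, y),
                            lambda y: _eh_deriv(p, y))


def _biex_lut(spec: TransformSpec):
    """Node grid (data values, scale values) for a FlowJo biexponential.

    The FlowJo parameters are mapped onto the biexponential family as
    T = max_value, M = pos_decades, W = log10(-width_basis)/2 (clamped to
    [0, M/2]), A = neg_decades (clamped to the family bound M - 2W).  The
    table spans scale values [2*x1 - 1, 1] so negative data down to
    -max_value are covered symmetrically.
    """
    T = float(spec.max_value)
    M = float(spec.pos_decades)
    wb = float(spec.width_basis)
    W = 0.0 if wb >= -1.0 else math.log10(-wb) / 2.0
    W = min(max(W, 0.0), M / 2.0)
    A = min(max(float(spec.neg_decades), 0.0), max(M - 2.0 * W, 0.0))
    p = _logicle_params(T, W, M, A)
    y_nodes = np.linspace(2.0 * p.x1 - 1.0, 1.0, BIEX_LUT_NODES)
    x_nodes = _biex_value(p, y_nodes)
    return x_nodes, y_nodes


def apply_flowjo_biex(values, spec: TransformSpec):
    """FlowJo biexponential via dense LUT + linear interpolation.

    Output is on the normalized [0, 1] scale (before any axis scaling);
    values outside [-max_value, max_value] clamp to the table ends.
    """
    validate_spec(spec)
    if spec.kind != "flowjo_biex":
        raise InvalidParams(f"expected flowjo_biex spec, got {spec.kind!r}")
    x_nodes, y_nodes = _biex_lut(spec)
    return np.interp(np.asarray(values, dtype=float), x_nodes, y_nodes)


def apply_ratio(events, channel_index: dict, spec: TransformSpec):
    """Channel-ratio derived parameter A*(num - B)/(den - C).

    ``events`` is the full [n_events x n_channels] matrix and
    ``channel_index`` maps channel name -> column.  Where the denominator
    equals C the result is +/-inf, propagated rather than trapped; callers
    can mask with ``np.isfinite``.
    """
    validate_spec(spec)
    if spec.kind != "ratio":
        raise InvalidParams(f"expected ratio spec, got {spec.kind!r}")
    for ch in (spec.num_channel, spec.den_channel):
        if ch not in channel_index:
            raise UnknownChannel(f"ratio channel {ch!r} not present in sample")
    ev = np.asarray(events, dtype=float)
    num = ev[:, channel_index[spec.num_channel]]
    den = ev[:, channel_index[spec.den_channel]]
    with np.errstate(divide="ignore", invalid="ignore"):
        return spec.A_r * (num - spec.B_r) / (den - spec.C_r)


def apply_transform(values, spec: TransformSpec):
    """Dispatch to the family-specific apply (ratio excluded: it needs a matrix)."""
    if spec.kind in ("linear", "log", "asinh"):
        return apply_closed_form(values, spec)
    if spec.kind == "logicle":
        return apply_logicle(values, spec)
    if spec.kind == "hyperlog":
        return apply_hyperlog(values, spec)
    if spec.kind == "flowjo_biex":
        return apply_flowjo_biex(values, spec)
    raise InvalidParams(f"apply_transform cannot handle kind {spec.kind!r} "
                        "(ratio needs the full event matrix; use apply_ratio)")


def invert_transform(values, spec: TransformSpec):
    """Map scale values back to data values.

    Closed forms for linear/log/asinh; direct evaluation of the
    biexponential generator for logicle/hyperlog; reversed table lookup for
    flowjo_biex.  The ratio transform is many-to-one and raises
    :class:`NotInvertible`.
    """
    validate_spec(spec)
    y = np.asarray(values, dtype=float)
    if spec.kind == "linear":
        return y * (spec.T + spec.A) - spec.A
    if spec.kind == "log":
        return spec.T * np.power(10.0, spec.M * (y - 1.0))
    if spec.kind == "asinh":
        m = spec.M * LN10
        return spec.T * np.sinh(y * (spec.M + spec.A) * LN10 - spec.A * LN10) / math.sinh(m)
    if spec.kind == "logicle":
        p = _logicle_params(spec.T, spec.W, spec.M, spec.A)
        return _biex_value(p, y)
    if spec.kind == "hyperlog":
        p = _hyperlog_params(spec.T, spec.W, spec.M, spec.A)
        return _eh_value(p, y)
    if spec.kind == "flowjo_biex":
        x_nodes, y_nodes = _biex_lut(spec)
        return np.interp(y, y_nodes, x_nodes)
    raise NotInvertible("ratio transforms are many-to-one and cannot be inverted")
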