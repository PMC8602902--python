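# Methods

This note records the models, numerical choices and design decisions
behind cytogate, and what the synthetic-data generator does and does not
emulate.

## FCS semantics

An FCS file is header + TEXT (keyword/value pairs between single-byte
delimiters, literal delimiters escaped by doubling) + DATA (+ optional
ANALYSIS). We read versions 2.0, 3.0 and 3.1 and always write 3.1 with
`$DATATYPE` F, little-endian, list mode and a single TEXT segment: content
(event values, `$PnN`, `$PnS`) is preserved across a write, the original
dialect is not.

Scaling on read follows FCS 3.1. For channel *n* with stored value *x*:

- log amplification `$PnE = f1,f2` with f1 > 0: value = f2·10^(f1·x/$PnR).
  The malformed-but-common `f1,0` is treated as f2 = 1 with a warning, and
  a simultaneous `$PnG` ≠ 1 is ignored (the two amplifications are mutually
  exclusive in the standard).
- otherwise: value = x / `$PnG`.
- the Time channel (detected by `$PnN` of `Time`/`time`, overridable) is
  multiplied by `$TIMESTEP` seconds.

Integer data may use different byte-aligned widths per channel
(8/16/24/32/64 bits); non-byte-aligned widths are rejected rather than
bit-stream-decoded. Stored integers are masked to the range implied by
`$PnR` (next power of two ≥ `$PnR`, minus one). A DATA segment whose
length is off by exactly ±1 byte relative to `$TOT`·`$PAR`·widths — a
defect class some instruments produce — is decoded anyway using the
declared `$TOT`, with a warning; larger discrepancies are fatal. Only the
first dataset of a multi-dataset file is read.

## Spillover and compensation

Orientation (stated because tools disagree): `S[i, j]` is the fraction of
fluorochrome *i*'s signal read by detector *j*; rows are normalized to a
unit diagonal. Observed = True·S, so compensation right-multiplies by
S⁻¹, implemented as a linear solve rather than an explicit inverse.
`$SPILLOVER` takes precedence over the legacy `$SPILL`. Matrices with
condition number above 1e12 are rejected as singular.

**Bead estimation.** For each single-stained file, events are split into
positive and negative populations at the midpoint of the 25th and 75th
percentiles of the stain channel. This midpoint rule captures each
cluster whole; a fixed cut at the 75th percentile would select only the
upper half of the positive cluster and bias its median up by ≈0.67σ
(and symmetrically for the negatives), a multiplicative error of order
2·0.67·σ/brightness in every coefficient — material at realistic noise.
The coefficient into detector *j* is
(median_pos(j) − median_neg(j)) / (median_pos(d) − median_neg(d)), with
the diagonal forced to 1 and negatives clamped to 0. A file whose
positive/negative gap on the stain channel does not exceed 5× the
within-population spread is rejected as effectively unstained. Medians
make the estimate robust to outliers; an optional unstained file supplies
per-channel background medians to subtract first. The scheme assumes
bright, well-separated beads; it is deterministic and replaceable.

## Transforms

All seven families map data values to a normalized display scale,
strictly increasing, with the top-of-scale value `T` mapping to 1 when
`A = 0`:

- linear: (x + A)/(T + A)
- log: log10(x/T)/M + 1; non-positive inputs yield −inf (a documented
  sentinel, so whole-matrix transforms never abort)
- asinh: (asinh(x·sinh(M·ln10)/T) + A·ln10)/((M + A)·ln10)
- ratio: A·(x_num − B)/(x_den − C); a denominator equal to C propagates
  ±inf rather than raising, maskable via `np.isfinite`; not invertible
- logicle: the inverse of the biexponential
  B(y) = a·e^{by} − c·e^{−dy} − f for y ≥ x1, extended by odd reflection
  about (x1, 0), where x1 = (A + W)/(M + A) is the scale position of data
  zero. The constants follow from T, W, M, A: b = (M + A)·ln10, *d* solves
  2(ln d − ln b) + w(b + d) = 0 with w = W/(M + A), and a, c, f are fixed
  by B(x1) = 0 and B(1) = T. Parameter bounds 0 ≤ W ≤ M/2 and
  −W ≤ A ≤ M − 2W are enforced before any computation.
- hyperlog: identical construction with the generator
  EH(y) = a·e^{by} + c·y − f (W > 0 required); EH's reflection makes the
  scale exactly odd-symmetric about the image of data zero.
- FlowJo biexponential: defined operationally, as the vendor does, by a
  lookup table. The FlowJo parameters map onto the family above as
  T = max_value, M = pos_decades, W = log10(−width_basis)/2 clamped to
  [0, M/2], A = neg_decades; 8,192 nodes span scale values [2·x1 − 1, 1]
  (so data in [−T, T] are covered) and evaluation is linear interpolation,
  invertible by reading the table backwards with round-trip error below
  1e-4·max_value. The exact vendor mapping from width basis to linear
  width is not published; round-trip fidelity is therefore asserted
  against this package's own definition, not against the FlowJo
  application.

**Root finding.** Logicle and hyperlog have no closed-form forward map;
each value is solved by bracketed bisection refined with Newton steps
(falling back to bisection whenever a Newton step leaves the bracket),
vectorized over the input, tolerance |B(y) − x| ≤ T·1e-13, cap 200
iterations. Negative inputs use the odd symmetry y(−x) = 2·x1 − y(x), so
only the upper branch is ever solved.

A known asymptotic: at W = 0, A = 0 the logicle reduces to
B(y) = 2a·sinh(by) and agrees with the log transform to within
e^{−2by}/b of scale; this is below 1e-6 over roughly the top two decades
and grows toward ~1e-5 two decades further down — a property of the
function itself, reflected in the tests.

## Gating model

A strategy is a registry of transforms and spillover matrices plus a tree
of gates addressed by full path (paths, not bare names, because the same
gate name legitimately recurs at different levels). Events enter gating
in the scaled ("raw") state; each gate dimension independently selects
compensation and transform, so samples are never pre-transformed
wholesale. Geometric gates are evaluated on all events and intersected
with the parent's membership — equivalent to evaluating on the parent
subset, and it keeps every membership vector full length.

Boundary semantics: boundaries belong to the gate everywhere. Rectangles
are closed intervals; polygon membership is the even-odd crossing-number
rule with an explicit on-segment check (tolerance 1e-12 of the vertex
scale) so edge and vertex points count as inside regardless of vertex
orientation; ellipsoids use ≤ on the squared Mahalanobis distance
(covariance validated symmetric positive-definite via Cholesky); quadrant
dividers send a value exactly equal to a split to the ≥ side, which makes
the cells an exact partition of the parent. Boolean gates may reference
only already-defined paths (forward references rejected), so insertion
order is a valid evaluation order and evaluation is single-pass and
deterministic. An empty parent gives children relative_percent 0 (the
0/0 convention).

One caveat on gate/transform interchange: axis-aligned rectangles commute
with any monotone per-axis transform (bounds map through the inverse),
but polygon *edges* are straight only in the space the polygon was drawn
in; under nonlinear transforms the two formulations genuinely differ near
edges. Gate coordinates therefore always live in the space declared by
their dimensions.

## Serialization

Gating-ML 2.0: the five gate elements, the six transform elements (flin,
flog, fasinh, logicle, hyperlog, fratio) and document-defined
spectrumMatrix compensation are supported; anything else raises a named
UnsupportedElement rather than being skipped. Gate ids are sanitized path
strings; a sidecar attribute in a private namespace preserves display
names. Numbers are serialized with shortest-round-trip float repr, so
read∘write is exact on parameters and write output is byte-deterministic.
The FlowJo biexponential is not expressible in Gating-ML and raises.

WSP (FlowJo 10) support is a documented subset: sample entries located by
file basename in a caller-supplied directory (URI paths are not trusted),
groups with one template gate tree each, compensation matrices and
transform declarations. Per-sample gate customizations inside a WSP are
rejected with a clear diagnostic, and unknown elements are collected into
a warnings list. Rectangle bounds, polygon vertices and quadrant splits
are stored in untransformed channel space (FlowJo's convention) and
converted through the declared transforms on read/write; ellipsoid
mean/covariance stay in transformed space because a quadratic form has no
exact pre-image under a nonlinear map. Legacy JO files are out of scope.

## Sessions, reports, CLI

A Session holds samples and named groups; each group has one template
strategy and optional per-sample gate overrides that exist only in memory
(WSP round-trips remain template-only). Results are cached per
(group, sample) and invalidated on any edit. Reports are long-format
tables (sample, gate_path, count, relative %, absolute %); an optional
CBC join adds absolute_count_per_ul = absolute_percent/100 ×
cells_per_ul, leaving base columns untouched and warning on missing join
keys. The CLI config file is YAML; its override syntax covers rectangle
gates only (other gate kinds are available through the API).

## Synthetic data

The generator exists so every pipeline stage is testable without
instrument data, and its defaults define the test conditions: mixture
samples with fixed fractions (the standard fixture is 60/30/10% at
n = 10,000), scatter channels as zero-truncated Gaussians, fluorescence
as Gaussians or lognormals in raw space over the usual ~0–262,144
range; bead sets as 50/50 negative/positive mixes with positive signal
`brightness` (default 10,000) times the true spill row plus Gaussian
noise of σ = 5% of brightness; and an FCS byte writer that can emit each
dialect and inject exactly one named defect (off-by-one length, mixed
integer widths, malformed `$PnE`). Every generator is a pure function of
(parameters, seed), and per-event truth labels make expected gate counts
exact. Not emulated: instrument noise spectra, doublets, time drift,
autofluorescence and spectral overlap beyond the linear spillover model —
so passing tests demonstrate correctness of the algorithms under the
stated model, not robustness to every artifact of real acquisitions.

## Problem sizes

The test suite and the acceptance script use 500–1,500-event samples for
round-trip and serialization checks, 10,000 events for population
recovery and bead estimation (50,000 in the estimator-consistency check),
1,000-point grids for transform residuals, and 50 random ≤5-gate
strategies × 1,000 events for the scalar-oracle equivalence — sizes at
which every quantity being measured is already stable.
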