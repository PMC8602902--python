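"""Spillover parsing, compensation, and bead-based matrix estimation.

Matrix orientation convention (documented prominently because tools
disagree): rows are source fluorochromes, columns are detectors, so entry
S[i, j] is the fraction of fluorochrome i's signal appearing in detector j
and the diagonal is 1.  Observed = True @ S, hence compensation is
right-multiplication by S^-1: X_comp = X @ inv(S).  This matches the FCS
3.1 ``$SPILLOVER`` keyword convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateBeads,
    HeaderMismatch,
    MalformedSpill,
    NonSquare,
    SingularMatrix,
    UnknownDetector,
)
from .fcs_io import Sample

log = logging.getLogger(__name__)

#: condition number above which a spillover matrix is treated as singular
_COND_LIMIT = 1e12


@dataclass
class SpilloverMatrix:
    """Named detectors plus a square spillover coefficient matrix."""

    detectors: list[str]
    matrix: np.ndarray
    id: str = "spill"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.detectors)
        if self.matrix.shape != (n, n):
            raise NonSquare(f"matrix shape {self.matrix.shape} for {n} detectors")
        self._normalize()

    def _normalize(self):
        diag = np.diag(self.matrix).copy()
        if np.any(diag == 0):
            raise SingularMatrix("spillover matrix has a zero diagonal entry")
        if not np.allclose(diag, 1.0):
            self.matrix = self.matrix / diag[:, None]
        if np.linalg.cond(self.matrix) > _COND_LIMIT:
            raise SingularMatrix("spillover matrix is singular or near-singular")

    @property
    def n(self) -> int:
        return len(self.detectors)

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def reordered(self, detectors: list[str]) -> "SpilloverMatrix":
        """Same spillover expressed with detectors in a different order."""
        if sorted(detectors) != sorted(self.detectors):
            raise UnknownDetector("reordering must use the same detector set")
        idx = [self.detectors.index(d) for d in detectors]
        return SpilloverMatrix(list(detectors), self.matrix[np.ix_(idx, idx)],
                               id=self.id)

    # -- serialization ------------------------------------------------------

    def to_spillover_keyword(self) -> str:
        toks = [str(self.n)] + list(self.detectors)
        toks += [f"{v:.12g}" for v in self.matrix.ravel()]
        return ",".join(toks)

    def to_csv(self, path=None) -> str:
        lines = [",".join(self.detectors)]
        for row in self.matrix:
            lines.append(",".join(f"{v:.12g}" for v in row))
        out = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(out)
        return out


def parse_spillover_keyword(value: str, id: str = "spill") -> SpilloverMatrix:
    """Parse the FCS 3.1 $SPILLOVER string "n,det1,...,detn,v11,...,vnn".

    Rows are normalized so every diagonal entry is 1.
    """
    toks = [t.strip() for t in value.strip().split(",")]
    try:
        n = int(toks[0])
    except (ValueError, IndexError):
        raise MalformedSpill(f"$SPILLOVER does not start with a count: {value[:40]!r}")
    if n < 1 or len(toks) != 1 + n + n * n:
        raise MalformedSpill(
            f"$SPILLOVER token count {len(toks)} inconsistent with n={n} "
            f"(expected {1 + n + n * n})")
    detectors = toks[1:1 + n]
    try:
        vals = np.array([float(t) for t in toks[1 + n:]], dtype=float)
    except ValueError:
        raise MalformedSpill("non-numeric coefficient in $SPILLOVER")
    return SpilloverMatrix(detectors, vals.reshape(n, n), id=id)


def parse_matrix_file(path, id: str | None = None) -> SpilloverMatrix:
    """Parse a comma- or tab-separated spillover matrix file.

    Format: one header row of detector names, then a square numeric body
    (the layout FlowJo uses for exported compensation matrices).
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise NonSquare(f"empty matrix file {path}")
    sep = "\t" if "\t" in lines[0] else ","
    detectors = [t.strip() for t in lines[0].split(sep)]
    # tolerate an empty leading header cell (row-label column)
    row_labels = detectors and detectors[0] == ""
    if row_labels:
        detectors = detectors[1:]
    n = len(detectors)
    body = lines[1:]
    if len(body) != n:
        raise NonSquare(f"{len(body)} body rows for {n} header detectors")
    rows = []
    for ln in body:
        toks = [t.strip() for t in ln.split(sep)]
        if row_labels:
            toks = toks[1:]
        if len(toks) != n:
            raise HeaderMismatch(f"row width {len(toks)} != header width {n}")
        try:
            rows.append([float(t) for t in toks])
        except ValueError:
            raise HeaderMismatch(f"non-numeric entry in matrix row: {ln!r}")
    return SpilloverMatrix(detectors, np.array(rows),
                           id=id or str(path).rsplit("/", 1)[-1])


def spillover_from_sample(sample: Sample, id: str = "fcs") -> SpilloverMatrix:
    """Extract the spillover matrix stored in a sample's FCS metadata.

    ``$SPILLOVER`` (FCS 3.1) takes precedence over the legacy ``$SPILL``.
    """
    for key in ("$SPILLOVER", "SPILLOVER", "$SPILL", "SPILL"):
        if key in sample.metadata:
            log.info("sample %s: using %s keyword for compensation",
                     sample.sample_id, key)
            return parse_spillover_keyword(sample.metadata[key], id=id)
    raise MalformedSpill(f"sample {sample.sample_id!r} carries no spillover keyword")


def apply_compensation(events_raw: np.ndarray, spill: SpilloverMatrix,
                       channel_map: dict[str, int]) -> np.ndarray:
    """Compensate the mapped detector columns; other columns pass through.

    ``channel_map`` maps each spillover detector name to its column in
    ``events_raw`` (scatter and time channels are simply left out of it).
    """
    cols = []
    for det in spill.detectors:
        if det not in channel_map:
            raise UnknownDetector(f"spill detector {det!r} not mapped to a channel")
        cols.append(channel_map[det])
    if len(set(cols)) != len(cols):
        raise UnknownDetector("two spill detectors map to the same channel column")
    out = np.array(events_raw, dtype=float, copy=True)
    sub = out[:, cols]
    # X_comp = X @ S^-1, solved as (S^T)^-1 X^T for numerical stability
    comp = np.linalg.solve(spill.matrix.T, sub.T).T
    out[:, cols] = comp
    return out


def compensate_sample(sample: Sample, spill: SpilloverMatrix) -> np.ndarray:
    """Compensate a sample in place (fills ``events_comp``) and return it."""
    cmap = {}
    for det in spill.detectors:
        try:
            cmap[det] = sample.channel_index(det)
        except KeyError:
            raise UnknownDetector(
                f"spill detector {det!r} not among sample channels "
                f"{sample.channel_names}")
    sample.events_comp = apply_compensation(sample.events_raw, spill, cmap)
    sample.applied_comp_ref = spill.id
    return sample.events_comp


def estimate_spillover_from_beads(bead_samples: list[Sample],
                                  stain_assignment: dict[str, Sample] | None = None,
                                  background_sample: Sample | None = None,
                                  detectors: list[str] | None = None,
                                  id: str = "bead-spill") -> SpilloverMatrix:
    """Estimate a spillover matrix from single-stained compensation beads.

    For each bead file stained for detector d, events are split into
    positive and negative populations at the midpoint of the 25th and 75th
    percentiles of channel d.  This captures each cluster whole (a fixed
    percentile cut such as >p75 would truncate the positive cluster at its
    median and bias the stain-channel median upward by ~0.67 sigma per
    side), is deterministic, and is adequate for bright beads.  The spill
    coefficient into detector j is

        S[d, j] = (median_pos(j) - median_neg(j)) / (median_pos(d) - median_neg(d))

    with the diagonal forced to 1 and negative estimates clamped to 0.  When
    ``background_sample`` is given its per-channel medians are subtracted
    first.
    """
    if stain_assignment is None:
        if detectors is None:
            raise UnknownDetector("provide stain_assignment or detectors list")
        stain_assignment = dict(zip(detectors, bead_samples))
    dets = detectors or list(stain_assignment)
    n = len(dets)
    S = np.eye(n)

    bg = None
    if background_sample is not None:
        bg_idx = [background_sample.channel_index(d) for d in dets]
        bg = np.median(background_sample.events_raw[:, bg_idx], axis=0)

    for i, d in enumerate(dets):
        smp = stain_assignment[d]
        idx = [smp.channel_index(x) for x in dets]
        ev = smp.events_raw[:, idx]
        if bg is not None:
            ev = ev - bg
        stain = ev[:, i]
        p25, p75 = np.percentile(stain, [25, 75])
        mid = 0.5 * (p25 + p75)
        pos = ev[stain > mid]
        neg = ev[stain <= mid]
        if len(pos) == 0 or len(neg) == 0:
            raise DegenerateBeads(f"bead file for {d!r}: empty positive or "
                                  "negative population")
        med_pos = np.median(pos, axis=0)
        med_neg = np.median(neg, axis=0)
        denom = med_pos[i] - med_neg[i]
        # separation criterion: the pos/neg median gap must dominate the
        # within-population spread, else the file is effectively unstained
        spread = max(float(np.std(pos[:, i])), float(np.std(neg[:, i])), 1e-12)
        if denom <= 0 or denom < 5.0 * spread:
            raise DegenerateBeads(
                f"bead file for {d!r}: positive and negative populations are "
                "not separated on the stain channel (unstained?)")
        row = (med_pos - med_neg) / denom
        row[i] = 1.0
        S[i] = np.clip(row, 0.0, None)
    return SpilloverMatrix(dets, S, id=id)
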