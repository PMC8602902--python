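"""Deterministic synthetic cytometry data with known ground truth.

Every generator here is a pure function of its parameters and a seed, so
tests and examples need no external data.  Scatter channels are simulated
as truncated (non-negative) Gaussians; fluorescence channels as lognormal
mixtures plus linear spillover in raw space, giving the ~0–262,144 dynamic
range real instruments produce.  Instrument noise spectra, doublets and
time drift are deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compensation import SpilloverMatrix
from .fcs_io import Sample, create_sample_from_matrix

DEFAULT_CHANNELS = ("FSC-A", "SSC-A", "FL1-A", "FL2-A", "FL3-A")

KNOWN_DEFECTS = ("off_by_one", "mixed_int_widths", "malformed_pne")


@dataclass(frozen=True)
class PopulationSpec:
    """One mixture component in raw channel space.

    ``mean`` and ``sd`` are per-channel; for channels flagged in
    ``lognormal``, ``mean`` is the population median and ``sd`` is the
    spread in log10 decades.  Gaussian channels are truncated at zero.
    """

    fraction: float
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    lognormal: tuple[bool, ...] | None = None

    def __post_init__(self):
        if not 0 < self.fraction <= 1:
            raise ValueError(f"population fraction must be in (0, 1], got {self.fraction}")
        if len(self.mean) != len(self.sd):
            raise ValueError("mean and sd must have equal length")
        if any(s < 0 for s in self.sd):
            raise ValueError("sd entries must be non-negative")
        if self.lognormal is not None and len(self.lognormal) != len(self.mean):
            raise ValueError("lognormal flags must match channel count")


def synth_sample(n_events: int, channels=DEFAULT_CHANNELS,
                 populations: list[PopulationSpec] | None = None,
                 seed: int = 0, sample_id: str = "synthetic"):
    """Draw a mixture sample; returns ``(Sample, labels)``.

    ``labels[i]`` is the index of the population that generated event i, so
    expected counts for any gate are computable from the truth directly.
    """
    channels = list(channels)
    if populations is None:
        k = len(channels)
        populations = [PopulationSpec(1.0, tuple([10000.0] * k), tuple([1500.0] * k))]
    total = sum(p.fraction for p in populations)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"population fractions sum to {total}, expected 1")
    for p in populations:
        if len(p.mean) != len(channels):
            raise ValueError("population mean length must match channel count")

    rng = np.random.default_rng(seed)
    labels = rng.choice(len(populations), size=n_events,
                        p=[p.fraction for p in populations])
    events = np.empty((n_events, len(channels)))
    for pi, pop in enumerate(populations):
        idx = np.flatnonzero(labels == pi)
        if idx.size == 0:
            continue
        for j in range(len(channels)):
            is_ln = bool(pop.lognormal[j]) if pop.lognormal is not None else False
            if is_ln:
                draw = np.power(10.0, rng.normal(np.log10(pop.mean[j]),
                                                 pop.sd[j], size=idx.size))
            else:
                draw = np.clip(rng.normal(pop.mean[j], pop.sd[j], size=idx.size),
                               0.0, None)
            events[idx, j] = draw
    sample = create_sample_from_matrix(events, channels, sample_id=sample_id)
    return sample, labels


def three_population_sample(n_events: int = 10000, seed: int = 7,
                            sample_id: str = "tri-pop"):
    """The standard 3-population fixture: fractions 60/30/10% on
    FSC/SSC/FL1/FL2, well-separated centroids; returns (Sample, labels)."""
    channels = ["FSC-A", "SSC-A", "FL1-A", "FL2-A"]
    pops = [
        PopulationSpec(0.60, (50000, 20000, 300, 200), (4000, 2500, 120, 100)),
        PopulationSpec(0.30, (90000, 60000, 20000, 500), (5000, 4000, 2500, 200)),
        PopulationSpec(0.10, (90000, 60000, 400, 30000), (5000, 4000, 150, 3500)),
    ]
    return synth_sample(n_events, channels, pops, seed=seed, sample_id=sample_id)


def synth_bead_set(spill: SpilloverMatrix, n_events: int = 10000,
                   brightness: float = 10000.0, noise_sd: float | None = None,
                   seed: int = 0):
    """Single-stained compensation bead files, one per detector.

    Each file is a 50/50 mix of negatives (pure noise around zero) and
    positives whose stain channel reads ``brightness`` and whose other
    channels read brightness x the true spill coefficients, all plus
    Gaussian noise of standard deviation ``noise_sd`` (default 5% of
    brightness).  Returns ``(bead_samples, unstained_sample)``.
    """
    if noise_sd is None:
        noise_sd = 0.05 * brightness
    rng = np.random.default_rng(seed)
    dets = spill.detectors
    n_det = spill.n
    beads = []
    for i, det in enumerate(dets):
        n_pos = n_events // 2
        signal = np.zeros((n_events, n_det))
        signal[:n_pos, :] = brightness * spill.matrix[i]   # row i: stain -> detectors
        ev = signal + rng.normal(0.0, noise_sd, size=(n_events, n_det))
        perm = rng.permutation(n_events)
        beads.append(create_sample_from_matrix(ev[perm], list(dets),
                                               sample_id=f"beads-{det}"))
    unstained = create_sample_from_matrix(
        rng.normal(0.0, noise_sd, size=(n_events, n_det)), list(dets),
        sample_id="beads-unstained")
    return beads, unstained


# --------------------------------------------------------------------------
# Dialect-controlled FCS byte generation (incl. deliberate defects)
# --------------------------------------------------------------------------

def _text_segment(pairs, delim="/"):
    parts = [delim]
    for k, v in pairs:
        parts.append(k.replace(delim, delim * 2) + delim
                     + str(v).replace(delim, delim * 2) + delim)
    return "".join(parts).encode("utf-8")


def synth_fcs_bytes(sample: Sample, dialect: str = "fcs3.1",
                    defects: set[str] | None = None) -> bytes:
    """Serialize a Sample's raw events in a chosen FCS dialect.

    ``dialect`` is one of ``fcs2.0`` (offsets in the header only),
    ``fcs3.0`` or ``fcs3.1`` (offsets also as $BEGINDATA/$ENDDATA).
    ``defects`` may inject exactly the named standards violations:

    * ``off_by_one``      — DATA segment declared one byte longer than it is
    * ``mixed_int_widths``— $DATATYPE I with per-channel $PnB of 16/32/24 bits
                            (values rounded to integers)
    * ``malformed_pne``   — last channel carries $PnE = "4,0" (f2 missing)
    """
    defects = set(defects or ())
    unknown = defects - set(KNOWN_DEFECTS)
    if unknown:
        raise ValueError(f"unknown defect name(s): {sorted(unknown)}")
    versions = {"fcs2.0": "FCS2.0", "fcs3.0": "FCS3.0", "fcs3.1": "FCS3.1"}
    if dialect not in versions:
        raise ValueError(f"dialect must be one of {sorted(versions)}, got {dialect!r}")

    events = sample.events_raw
    n_events, n_par = events.shape

    if "mixed_int_widths" in defects:
        datatype = "I"
        widths_bits = [(16, 32, 24)[i % 3] for i in range(n_par)]
        cols = []
        ranges = []
        for j, bits in enumerate(widths_bits):
            cap = (1 << bits) - 1
            col = np.clip(np.round(events[:, j]), 0, cap).astype(np.uint64)
            cols.append(col)
            ranges.append(1 << bits)
        event_size = sum(b // 8 for b in widths_bits)
        buf = bytearray()
        for r in range(n_events):
            for j, bits in enumerate(widths_bits):
                buf += int(cols[j][r]).to_bytes(bits // 8, "little")
        data_bytes = bytes(buf)
    else:
        datatype = "F"
        widths_bits = [32] * n_par
        ranges = [max(p.range, float(np.max(events[:, j], initial=0.0)) + 1)
                  for j, p in enumerate(sample.params)]
        data_bytes = np.ascontiguousarray(events, dtype="<f4").tobytes()

    pairs = [
        ("$MODE", "L"), ("$DATATYPE", datatype), ("$BYTEORD", "1,2,3,4"),
        ("$NEXTDATA", "0"),
        ("$TOT", str(n_events)), ("$PAR", str(n_par)),
    ]
    for i, p in enumerate(sample.params, start=1):
        pne = "0,0"
        if "malformed_pne" in defects and i == n_par:
            pne = "4,0"
        pairs += [(f"$P{i}N", p.pnn), (f"$P{i}B", str(widths_bits[i - 1])),
                  (f"$P{i}E", pne), (f"$P{i}R", f"{ranges[i - 1]:g}")]
        if p.pns is not None:
            pairs.append((f"$P{i}S", p.pns))

    use_text_offsets = dialect in ("fcs3.0", "fcs3.1")
    begin_data = 0
    text = b""
    for _ in range(10):
        extra = []
        if use_text_offsets:
            extra = [("$BEGINDATA", str(begin_data)),
                     ("$ENDDATA", str(begin_data + len(data_bytes) - 1
                                      if data_bytes else begin_data)),
                     ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
                     ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0")]
        text = _text_segment(pairs + extra)
        new_begin = 58 + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin

    data_end = begin_data + len(data_bytes) - 1 if data_bytes else begin_data
    declared_end = data_end
    tail = b""
    if "off_by_one" in defects:
        declared_end += 1          # declare one byte too many...
        tail = b"\x00"             # ...and pad so the slice really is longer

    def hfield(v):
        return str(v).rjust(8).encode("ascii")

    hdr = versions[dialect].ljust(10).encode("ascii")
    hdr += hfield(58) + hfield(58 + len(text) - 1)
    hdr += hfield(begin_data) + hfield(declared_end)
    hdr += hfield(0) + hfield(0)
    return hdr + text + data_bytes + tail
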