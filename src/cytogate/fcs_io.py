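"""Reading and writing Flow Cytometry Standard (FCS) files.

Supports reading FCS 2.0, 3.0 and 3.1 list-mode files with integer (variable
byte-aligned widths), 32-bit float and 64-bit float data, and writing FCS 3.1
(``$DATATYPE`` F, little-endian, single TEXT segment) plus CSV export.

Standards-correct scaling is applied on read: linear gain (``$PnG``,
stored / gain), log amplification (``$PnE`` = "f1,f2", value =
f2 * 10^(f1 * x / $PnR)), and the time step (``$TIMESTEP`` seconds per Time
channel unit).  Files that violate the standard with the common off-by-one
error in the declared DATA length are accepted with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateChannelName,
    InvalidAmplification,
    LengthMismatch,
    MalformedHeader,
    MissingRequiredKeyword,
    NTooLarge,
    ShapeMismatch,
    SourceUnavailable,
    UnsupportedBitWidth,
    UnsupportedVersion,
    UnterminatedValue,
    FCSError,
)

log = logging.getLogger(__name__)

SUPPORTED_VERSIONS = ("FCS2.0", "FCS3.0", "FCS3.1")
REQUIRED_KEYWORDS = ("$TOT", "$PAR", "$DATATYPE", "$BYTEORD", "$MODE")
EVENT_SOURCES = ("orig", "raw", "comp", "xform")


@dataclass
class FCSHeader:
    """Decoded 58-byte FCS header: version string and six segment offsets.

    An offset of 0 means absent (ANALYSIS) or overflowed into the TEXT
    keywords ($BEGINDATA/$ENDDATA), per FCS 3.x.
    """

    version_string: str
    text_begin: int
    text_end: int
    data_begin: int
    data_end: int
    analysis_begin: int
    analysis_end: int


@dataclass
class ParameterInfo:
    """Per-channel acquisition metadata ($Pn* keywords)."""

    index: int                       # 1-based channel index
    pnn: str                         # $PnN short name
    pns: str | None = None           # $PnS stain label
    bits: int = 32                   # $PnB
    range: float = 262144.0          # $PnR
    amplification: tuple[float, float] = (0.0, 0.0)   # $PnE (f1, f2)
    gain: float = 1.0                # $PnG
    is_time: bool = False

    def __post_init__(self):
        f1, f2 = self.amplification
        if f1 > 0 and f2 == 0:
            # widely produced malformed $PnE "f1,0": treat f2 as 1
            log.warning("channel %s: $PnE '%g,0' with f1 > 0; treating f2 as 1.0",
                        self.pnn, f1)
            self.amplification = (f1, 1.0)


class Sample:
    """One FCS acquisition: metadata, channel info and event matrices.

    Event data exists in up to four states sharing the shape
    [n_events x n_channels]:

    * ``orig``  — values as decoded from the DATA segment
    * ``raw``   — after gain / log-amplification / timestep scaling
    * ``comp``  — after spillover compensation (optional)
    * ``xform`` — after display transforms (optional)
    """

    def __init__(self, sample_id: str, metadata: dict, params: list[ParameterInfo],
                 events_orig: np.ndarray, events_raw: np.ndarray,
                 timestep: float = 1.0, verbatim_keys: dict | None = None):
        if events_orig.shape != events_raw.shape:
            raise ShapeMismatch("orig and raw event matrices differ in shape")
        if events_orig.ndim != 2 or events_orig.shape[1] != len(params):
            raise ShapeMismatch(
                f"event matrix has {events_orig.shape[1] if events_orig.ndim == 2 else '?'}"
                f" columns but {len(params)} parameters")
        self.sample_id = sample_id
        self.metadata = metadata
        self.verbatim_keys = verbatim_keys or {}
        self.params = params
        self.events_orig = events_orig
        self.events_raw = events_raw
        self.events_comp: np.ndarray | None = None
        self.events_xform: np.ndarray | None = None
        self.timestep = timestep
        self.applied_comp_ref: str | None = None
        self.applied_xform_refs: dict[str, str] = {}
        self.subsample_indices: np.ndarray | None = None

    # -- basic introspection ------------------------------------------------

    @property
    def n_events(self) -> int:
        return self.events_orig.shape[0]

    @property
    def n_channels(self) -> int:
        return self.events_orig.shape[1]

    @property
    def channel_names(self) -> list[str]:
        return [p.pnn for p in self.params]

    def channel_index(self, pnn: str) -> int:
        for i, p in enumerate(self.params):
            if p.pnn == pnn:
                return i
        raise KeyError(f"no channel named {pnn!r}")

    def get_events(self, source: str = "raw") -> np.ndarray:
        if source not in EVENT_SOURCES:
            raise ValueError(f"source must be one of {EVENT_SOURCES}, got {source!r}")
        m = {"orig": self.events_orig, "raw": self.events_raw,
             "comp": self.events_comp, "xform": self.events_xform}[source]
        if m is None:
            raise SourceUnavailable(
                f"event source {source!r} has not been computed for sample "
                f"{self.sample_id!r}")
        return m

    def as_dataframe(self, source: str = "raw") -> pd.DataFrame:
        return pd.DataFrame(self.get_events(source), columns=self.channel_names)

    def __repr__(self):
        return (f"Sample({self.sample_id!r}, {self.n_events} events x "
                f"{self.n_channels} channels)")


# --------------------------------------------------------------------------
# Low-level parsing operations
# --------------------------------------------------------------------------

def parse_header(first_bytes: bytes) -> FCSHeader:
    """Decode the 58-byte FCS header (version + six ASCII offsets)."""
    if len(first_bytes) < 58:
        raise MalformedHeader(f"header needs >= 58 bytes, got {len(first_bytes)}")
    version = first_bytes[0:6].decode("ascii", errors="replace").strip()
    if version not in SUPPORTED_VERSIONS:
        raise UnsupportedVersion(
            f"version {version!r} is not supported (FCS 2.0/3.0/3.1 only)")

    offsets = []
    for i in range(6):
        fld = first_bytes[10 + 8 * i: 18 + 8 * i].decode("ascii", errors="replace")
        s = fld.strip()
        if s == "":
            offsets.append(0)
        else:
            try:
                offsets.append(int(s))
            except ValueError:
                raise MalformedHeader(f"non-numeric header offset field {fld!r}")
    return FCSHeader(version, *offsets)


def parse_text_segment(segment: bytes, require_keywords: bool = False):
    """Parse a TEXT segment into keyword tables.

    Returns ``(keywords, verbatim_keys, delimiter)`` where ``keywords`` maps
    case-normalized (upper) keys to values, and ``verbatim_keys`` maps each
    normalized key back to its original spelling for round-trip writes.
    Doubled delimiters inside values un-escape to one literal delimiter.
    """
    if not segment:
        raise UnterminatedValue("empty TEXT segment")
    delim = segment[0:1]
    body = segment[1:]
    # strip trailing padding after the final delimiter
    end = body.rfind(delim)
    if end < 0:
        raise UnterminatedValue("TEXT segment contains no terminating delimiter")
    body = body[:end + 1]

    tokens: list[str] = []
    cur = bytearray()
    i = 0
    n = len(body)
    while i < n:
        ch = body[i:i + 1]
        if ch == delim:
            if i + 1 < n and body[i + 1:i + 2] == delim:
                cur += delim          # escaped literal delimiter
                i += 2
                continue
            tokens.append(cur.decode("utf-8", errors="replace"))
            cur = bytearray()
            i += 1
        else:
            cur += ch
            i += 1
    if cur:
        raise UnterminatedValue("TEXT segment ended inside a value")
    if len(tokens) % 2 != 0:
        raise UnterminatedValue("odd number of TEXT tokens (key without value)")

    keywords: dict[str, str] = {}
    verbatim: dict[str, str] = {}
    for k, v in zip(tokens[0::2], tokens[1::2]):
        key = k.strip().upper()
        keywords[key] = v
        verbatim[key] = k.strip()
    if require_keywords:
        for req in REQUIRED_KEYWORDS:
            if req not in keywords:
                raise MissingRequiredKeyword(f"required keyword {req} absent from TEXT")
    return keywords, verbatim, delim.decode("ascii")


def _int_mask(pnr: float, bits: int) -> int | None:
    """Bit mask implied by $PnR: next power of two >= $PnR, minus 1."""
    if pnr is None or pnr <= 0:
        return None
    mask = (1 << max(1, math.ceil(math.log2(pnr)))) - 1
    full = (1 << bits) - 1
    return mask if mask < full else None


def decode_data(data: bytes, params: list[ParameterInfo], datatype: str,
                byteorder: str, n_events: int) -> np.ndarray:
    """Decode a DATA segment into an [n_events x n_params] float matrix.

    Integer data may use different byte-aligned widths per parameter; stored
    values are masked to the bit range implied by ``$PnR``.  A data segment
    whose length is off by exactly one byte (a known defect class in the
    wild) is decoded anyway using the declared ``$TOT``.
    """
    n_par = len(params)
    if datatype not in ("I", "F", "D"):
        raise FCSError(f"unsupported $DATATYPE {datatype!r}")
    if byteorder not in ("little", "big"):
        raise ValueError("byteorder must be 'little' or 'big'")

    if datatype == "I":
        widths = []
        for p in params:
            if p.bits % 8 != 0 or p.bits not in (8, 16, 24, 32, 64):
                raise UnsupportedBitWidth(
                    f"channel {p.pnn}: $PnB={p.bits} is not a supported "
                    "byte-aligned width (8/16/24/32/64)")
            widths.append(p.bits // 8)
        event_size = sum(widths)
    else:
        width = 4 if datatype == "F" else 8
        widths = [width] * n_par
        event_size = width * n_par

    expected = event_size * n_events
    if len(data) != expected:
        if abs(len(data) - expected) == 1:
            log.warning("DATA segment length %d differs from expected %d by one "
                        "byte; decoding %d declared events anyway",
                        len(data), expected, n_events)
            data = data[:expected] if len(data) > expected else data
            if len(data) < expected:
                raise LengthMismatch(
                    f"DATA segment one byte short ({len(data)} < {expected})")
        else:
            raise LengthMismatch(
                f"DATA segment is {len(data)} bytes; expected {expected} "
                f"for {n_events} events x {event_size} bytes")

    if n_events == 0:
        return np.empty((0, n_par), dtype=float)

    if datatype in ("F", "D"):
        dt = np.dtype(("<" if byteorder == "little" else ">") +
                      ("f4" if datatype == "F" else "f8"))
        mat = np.frombuffer(data, dtype=dt, count=n_events * n_par)
        return mat.reshape(n_events, n_par).astype(float)

    # integer: possibly mixed widths -> decode from raw bytes
    raw = np.frombuffer(data, dtype=np.uint8, count=n_events * event_size)
    raw = raw.reshape(n_events, event_size)
    out = np.empty((n_events, n_par), dtype=float)
    col = 0
    for j, (p, w) in enumerate(zip(params, widths)):
        chunk = raw[:, col:col + w].astype(np.uint64)
        col += w
        val = np.zeros(n_events, dtype=np.uint64)
        order = range(w) if byteorder == "little" else range(w - 1, -1, -1)
        for shift, b in enumerate(order):
            val |= chunk[:, b] << np.uint64(8 * shift)
        mask = _int_mask(p.range, p.bits)
        if mask is not None:
            val &= np.uint64(mask)
        out[:, j] = val.astype(float)
    return out


def scale_events(events_orig: np.ndarray, params: list[ParameterInfo],
                 timestep: float = 1.0) -> np.ndarray:
    """Apply gain / log-amplification / timestep scaling per channel.

    For a channel with ``$PnE`` = (f1, f2), f1 > 0:
    value = f2 * 10^(f1 * x / $PnR).  Otherwise value = x / $PnG.  The Time
    channel is additionally multiplied by ``$TIMESTEP``.  Identity when all
    gains are 1, all f1 = 0 and timestep = 1.
    """
    out = np.array(events_orig, dtype=float, copy=True)
    for j, p in enumerate(params):
        f1, f2 = p.amplification
        if f1 > 0:
            if p.range is None or p.range <= 0:
                raise InvalidAmplification(
                    f"channel {p.pnn}: $PnE f1={f1} requires $PnR > 0")
            out[:, j] = f2 * np.power(10.0, f1 * out[:, j] / p.range)
        elif p.gain != 1.0:
            out[:, j] = out[:, j] / p.gain
        if p.is_time:
            out[:, j] = out[:, j] * timestep
    return out


# --------------------------------------------------------------------------
# Whole-file read / write
# --------------------------------------------------------------------------

def _build_params(kw: dict, time_channel: str | None = None) -> list[ParameterInfo]:
    n_par = int(kw["$PAR"])
    params = []
    for i in range(1, n_par + 1):
        pnn = kw.get(f"$P{i}N", f"P{i}")
        pne = kw.get(f"$P{i}E", "0,0")
        try:
            f1, f2 = (float(t) for t in pne.split(","))
        except ValueError:
            raise FCSError(f"malformed $P{i}E value {pne!r}")
        gain = float(kw.get(f"$P{i}G", 1.0))
        if f1 > 0 and gain != 1.0:
            # log and linear amplification are mutually exclusive (FCS 3.1)
            log.warning("channel %s declares both $PnE log amplification and "
                        "$PnG=%g; ignoring gain", pnn, gain)
            gain = 1.0
        if time_channel is not None:
            is_time = pnn == time_channel
        else:
            is_time = pnn in ("Time", "time")
        params.append(ParameterInfo(
            index=i,
            pnn=pnn,
            pns=kw.get(f"$P{i}S"),
            bits=int(kw.get(f"$P{i}B", 32)),
            range=float(kw.get(f"$P{i}R", 262144)),
            amplification=(f1, f2),
            gain=gain,
            is_time=is_time,
        ))
    return params


def read_fcs(path, sample_id: str | None = None,
             time_channel: str | None = None) -> Sample:
    """Read an FCS 2.0/3.0/3.1 file into a :class:`Sample`.

    Honors ``$BEGINDATA``/``$ENDDATA`` when the header data offsets are 0.
    Only the first dataset of a multi-dataset file is read ($NEXTDATA != 0
    produces a warning).
    """
    if isinstance(path, (bytes, bytearray)):
        blob = bytes(path)
        name = sample_id or "in-memory"
    else:
        with open(path, "rb") as fh:
            blob = fh.read()
        name = sample_id or str(path).rsplit("/", 1)[-1]

    header = parse_header(blob[:58])
    kw, verbatim, _delim = parse_text_segment(
        blob[header.text_begin:header.text_end + 1], require_keywords=True)

    data_begin, data_end = header.data_begin, header.data_end
    if data_begin == 0 or data_end == 0:
        try:
            data_begin = int(kw["$BEGINDATA"])
            data_end = int(kw["$ENDDATA"])
        except KeyError:
            raise MissingRequiredKeyword(
                "header data offsets are 0 and $BEGINDATA/$ENDDATA are absent")

    if int(kw.get("$NEXTDATA", 0)) != 0:
        log.warning("%s: multi-dataset file ($NEXTDATA != 0); reading only "
                    "the first dataset", name)
    mode = kw.get("$MODE", "L")
    if mode != "L":
        raise FCSError(f"only list mode ($MODE L) is supported, got {mode!r}")

    datatype = kw["$DATATYPE"]
    byteorder = "little" if kw["$BYTEORD"].strip().startswith("1") else "big"
    n_events = int(kw["$TOT"])
    params = _build_params(kw, time_channel=time_channel)
    timestep = float(kw.get("$TIMESTEP", 1.0))

    data = blob[data_begin:data_end + 1]
    events_orig = decode_data(data, params, datatype, byteorder, n_events)
    events_raw = scale_events(events_orig, params, timestep)
    return Sample(name, kw, params, events_orig, events_raw,
                  timestep=timestep, verbatim_keys=verbatim)


def create_sample_from_matrix(events, channel_names: list[str],
                              labels: list[str] | None = None,
                              sample_id: str = "in-memory") -> Sample:
    """Build a Sample from an in-memory matrix (no file involved).

    ``events`` becomes both the orig and raw state (gain 1, no
    amplification); ``labels`` optionally supplies $PnS stain labels.
    """
    ev = np.asarray(events, dtype=float)
    if ev.ndim != 2:
        raise ShapeMismatch("events must be a 2-D matrix")
    if len(channel_names) != ev.shape[1]:
        raise ShapeMismatch(f"{len(channel_names)} channel names for "
                            f"{ev.shape[1]} matrix columns")
    if len(set(channel_names)) != len(channel_names):
        raise DuplicateChannelName(f"channel names not unique: {channel_names}")
    if labels is not None and len(labels) != len(channel_names):
        raise ShapeMismatch("labels length must match channel_names")

    params = []
    for i, pnn in enumerate(channel_names):
        col_max = float(ev[:, i].max()) if ev.size else 0.0
        rng = max(262144.0, math.ceil(col_max) + 1)
        params.append(ParameterInfo(
            index=i + 1, pnn=pnn,
            pns=labels[i] if labels else None,
            bits=32, range=rng, amplification=(0.0, 0.0), gain=1.0,
            is_time=pnn in ("Time", "time")))
    kw = {"$TOT": str(ev.shape[0]), "$PAR": str(ev.shape[1]),
          "$DATATYPE": "F", "$BYTEORD": "1,2,3,4", "$MODE": "L"}
    return Sample(sample_id, kw, params, ev.copy(), ev.copy())


def write_fcs(sample: Sample, source: str = "raw", path=None) -> bytes:
    """Write one event state of a Sample as an FCS 3.1 file.

    Always emits ``$DATATYPE`` F, little-endian, list mode, a single TEXT
    segment and no ANALYSIS segment, regardless of the input dialect;
    content (event values, $PnN, $PnS) is preserved, dialect is not.
    Returns the bytes; writes them to ``path`` when given.
    """
    events = sample.get_events(source)          # raises SourceUnavailable
    n_events, n_par = events.shape
    data_bytes = np.ascontiguousarray(events, dtype="<f4").tobytes()

    kw_pairs: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
        ("$NEXTDATA", "0"),
        ("$MODE", "L"), ("$DATATYPE", "F"), ("$BYTEORD", "1,2,3,4"),
        ("$TOT", str(n_events)), ("$PAR", str(n_par)),
    ]
    for i, p in enumerate(sample.params, start=1):
        # written data is already fully scaled: unit gain, no amplification
        rng = max(p.range, float(np.max(events[:, i - 1], initial=0.0)) + 1)
        kw_pairs += [(f"$P{i}N", p.pnn), (f"$P{i}B", "32"),
                     (f"$P{i}E", "0,0"), (f"$P{i}R", f"{rng:g}")]
        if p.pns is not None:
            kw_pairs.append((f"$P{i}S", p.pns))

    delim = "/"

    def esc(v: str) -> str:
        return v.replace(delim, delim + delim)

    # $BEGINDATA/$ENDDATA depend on TEXT length; iterate until stable
    begin_data = 0
    for _ in range(10):
        parts = [delim]
        for k, v in kw_pairs + [("$BEGINDATA", str(begin_data)),
                                ("$ENDDATA", str(begin_data + len(data_bytes) - 1
                                                 if data_bytes else begin_data))]:
            parts.append(f"{esc(k)}{delim}{esc(v) if v else ' '}{delim}")
        text = "".join(parts).encode("utf-8")
        new_begin = 58 + len(text)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    text_begin = 58
    text_end = text_begin + len(text) - 1
    data_end = begin_data + len(data_bytes) - 1 if data_bytes else begin_data

    def hfield(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"       # overflow: offsets live in TEXT keywords
        return s.rjust(8).encode("ascii")

    hdr = b"FCS3.1    " + hfield(text_begin) + hfield(text_end)
    hdr += hfield(begin_data if data_end <= 99999999 else 0)
    hdr += hfield(data_end if data_end <= 99999999 else 0)
    hdr += hfield(0) + hfield(0)
    blob = hdr + text + data_bytes
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(blob)
    return blob


def export_csv(sample: Sample, source: str = "raw", path=None) -> str:
    """Export one event state as RFC-4180 CSV ($PnN header + one row/event)."""
    df = sample.as_dataframe(source)
    out = df.to_csv(index=False, lineterminator="\r\n")
    if path is not None:
        with open(path, "w", newline="") as fh:
            fh.write(out)
    return out


def subsample_events(sample: Sample, n: int, seed: int) -> np.ndarray:
    """Draw n distinct event indices uniformly without replacement.

    The sorted index vector is stored on the sample (``subsample_indices``)
    so downstream exports can honor it; reproducible for a fixed seed.
    """
    if n < 0 or n > sample.n_events:
        raise NTooLarge(f"cannot subsample {n} of {sample.n_events} events")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(sample.n_events, size=n, replace=False))
    sample.subsample_indices = idx
    return idx
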