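"""FCS parsing, scaling and writing: header/TEXT/DATA semantics, dialect
round-trips, defect tolerance, and in-memory sample construction."""

import numpy as np
import pytest

from cytogate import fcs_io, synth
from cytogate.exceptions import (
    DuplicateChannelName,
    LengthMismatch,
    MalformedHeader,
    NTooLarge,
    ShapeMismatch,
    SourceUnavailable,
    UnsupportedBitWidth,
    UnsupportedVersion,
)
from cytogate.fcs_io import (
    ParameterInfo,
    create_sample_from_matrix,
    decode_data,
    parse_header,
    parse_text_segment,
    read_fcs,
    scale_events,
    subsample_events,
    write_fcs,
)


def header_bytes(version="FCS3.1", offsets=(58, 1024, 1025, 9024, 0, 0)):
    out = version.ljust(10)
    for off in offsets:
        out += str(off).rjust(8) if off != "" else " " * 8
    return out.encode("ascii")


class TestHeader:
    def test_direct_field_decode(self):
        h = parse_header(header_bytes())
        assert h.version_string == "FCS3.1"
        assert (h.text_begin, h.text_end) == (58, 1024)
        assert (h.data_begin, h.data_end) == (1025, 9024)
        assert (h.analysis_begin, h.analysis_end) == (0, 0)

    def test_blank_analysis_fields_yield_zero(self):
        h = parse_header(header_bytes(offsets=(58, 1024, 1025, 9024, "", "")))
        assert h.analysis_begin == 0 and h.analysis_end == 0

    def test_unsupported_version(self):
        with pytest.raises(UnsupportedVersion):
            parse_header(header_bytes(version="FCS9.9"))

    def test_non_numeric_offset(self):
        bad = header_bytes()[:18] + b"12ab5678" + header_bytes()[26:]
        with pytest.raises(MalformedHeader):
            parse_header(bad)

    def test_writer_header_offsets_roundtrip(self, small_sample):
        blob = write_fcs(small_sample, "raw")
        h = parse_header(blob[:58])
        kw, _, _ = parse_text_segment(blob[h.text_begin:h.text_end + 1])
        assert int(kw["$BEGINDATA"]) == h.data_begin
        assert int(kw["$ENDDATA"]) == h.data_end


class TestTextSegment:
    def test_direct_parse(self):
        kw, _, delim = parse_text_segment(b"/$TOT/100/$PAR/3/")
        assert delim == "/"
        assert kw == {"$TOT": "100", "$PAR": "3"}

    def test_doubled_delimiter_unescapes(self):
        kw, _, _ = parse_text_segment(b"/$FIL/a//b/")
        assert kw["$FIL"] == "a/b"

    def test_roundtrip_through_writer(self, small_sample):
        blob = write_fcs(small_sample, "raw")
        h = parse_header(blob[:58])
        kw, _, _ = parse_text_segment(blob[h.text_begin:h.text_end + 1])
        n_kw = len(kw)
        s2 = read_fcs(blob)
        blob2 = write_fcs(s2, "raw")
        h2 = parse_header(blob2[:58])
        kw2, _, _ = parse_text_segment(blob2[h2.text_begin:h2.text_end + 1])
        assert kw2 == kw and len(kw2) == n_kw


def _params(n, bits=32, rng=262144):
    return [ParameterInfo(index=i + 1, pnn=f"P{i + 1}", bits=bits, range=rng)
            for i in range(n)]


class TestDecodeData:
    def test_float32_constructed_bytes(self):
        mat = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        data = mat.astype("<f4").tobytes()
        out = decode_data(data, _params(2), "F", "little", 3)
        assert np.array_equal(out, mat)

    def test_integer_masked_to_pnr_bits(self):
        # scalar bit-mask oracle: next power of two >= $PnR, minus one
        pnr = 1024
        mask = (1 << int(np.ceil(np.log2(pnr)))) - 1
        assert 1025 & mask == 1
        params = [ParameterInfo(index=1, pnn="P1", bits=16, range=pnr)]
        data = (1025).to_bytes(2, "little")
        out = decode_data(data, params, "I", "little", 1)
        assert out[0, 0] == 1.0

    def test_off_by_one_long_segment_decodes(self, caplog):
        mat = np.array([[1.0, 2.0]])
        data = mat.astype("<f4").tobytes() + b"\x00"
        with caplog.at_level("WARNING"):
            out = decode_data(data, _params(2), "F", "little", 1)
        assert np.array_equal(out, mat)
        assert any("one byte" in r.message for r in caplog.records)

    def test_larger_mismatch_fatal(self):
        with pytest.raises(LengthMismatch):
            decode_data(b"\x00" * 11, _params(2), "F", "little", 1)

    def test_non_byte_aligned_width_rejected(self):
        params = [ParameterInfo(index=1, pnn="P1", bits=10, range=1024)]
        with pytest.raises(UnsupportedBitWidth):
            decode_data(b"\x00\x00", params, "I", "little", 1)

    def test_float64_exact_roundtrip(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(50, 3))
        out = decode_data(mat.astype("<f8").tobytes(), _params(3), "D",
                          "little", 50)
        assert np.array_equal(out, mat)

    def test_big_endian_integers(self):
        params = [ParameterInfo(index=1, pnn="P1", bits=24, range=1 << 24)]
        data = (0x010203).to_bytes(3, "big")
        out = decode_data(data, params, "I", "big", 1)
        assert out[0, 0] == float(0x010203)


class TestScaleEvents:
    def test_gain_divides(self):
        p = [ParameterInfo(index=1, pnn="FL1", gain=2.0)]
        assert scale_events(np.array([[500.0]]), p)[0, 0] == 250.0

    def test_log_amplification(self):
        p = [ParameterInfo(index=1, pnn="FL1", range=1024,
                           amplification=(4.0, 1.0))]
        assert scale_events(np.array([[1024.0]]), p)[0, 0] == pytest.approx(10000.0)

    def test_timestep_multiplies_time_channel(self):
        p = [ParameterInfo(index=1, pnn="Time", is_time=True)]
        assert scale_events(np.array([[100.0]]), p, timestep=0.01)[0, 0] == \
            pytest.approx(1.0)

    def test_identity_when_all_defaults(self):
        rng = np.random.default_rng(1)
        mat = rng.uniform(0, 1000, (20, 3))
        out = scale_events(mat, _params(3), timestep=1.0)
        assert np.array_equal(out, mat)

    def test_malformed_pne_f2_treated_as_one(self, caplog):
        with caplog.at_level("WARNING"):
            p = ParameterInfo(index=1, pnn="FL1", range=1024,
                              amplification=(4.0, 0.0))
        assert p.amplification == (4.0, 1.0)


class TestReadWrite:
    @pytest.mark.parametrize("dialect", ["fcs2.0", "fcs3.0", "fcs3.1"])
    def test_dialects_decode_identically(self, dialect, small_sample):
        blob = synth.synth_fcs_bytes(small_sample, dialect)
        s = read_fcs(blob, sample_id=dialect)
        assert s.n_events == small_sample.n_events
        assert s.channel_names == small_sample.channel_names
        assert np.allclose(s.events_raw,
                           small_sample.events_raw.astype(np.float32),
                           rtol=1e-6)

    def test_write_read_roundtrip(self, small_sample):
        s2 = read_fcs(write_fcs(small_sample, "raw"))
        denom = np.abs(small_sample.events_raw) + 1.0
        assert np.max(np.abs(s2.events_raw - small_sample.events_raw) / denom) < 1e-6
        assert s2.channel_names == small_sample.channel_names

    def test_pns_labels_roundtrip(self):
        s = create_sample_from_matrix(np.ones((2, 2)), ["FL1-A", "FL2-A"],
                                      labels=["CD3 FITC", "CD4 PE"])
        s2 = read_fcs(write_fcs(s, "raw"))
        assert [p.pns for p in s2.params] == ["CD3 FITC", "CD4 PE"]

    def test_zero_event_file(self):
        s = create_sample_from_matrix(np.empty((0, 2)), ["A", "B"])
        s2 = read_fcs(write_fcs(s, "raw"))
        assert s2.n_events == 0 and s2.n_channels == 2

    def test_comp_before_compensation_unavailable(self, small_sample):
        with pytest.raises(SourceUnavailable):
            write_fcs(small_sample, "comp")

    def test_export_csv_line_count(self):
        s = create_sample_from_matrix(np.ones((3, 2)), ["A", "B"])
        text = fcs_io.export_csv(s, "raw")
        assert len(text.strip().splitlines()) == 4    # header + 3 events


class TestCreateSample:
    def test_identity_export(self):
        mat = np.array([[1.0, 2.0], [3.0, 4.0]])
        s = create_sample_from_matrix(mat, ["FSC-A", "SSC-A"])
        assert np.array_equal(s.events_raw, mat)
        assert np.array_equal(s.events_orig, mat)

    def test_duplicate_names_rejected(self):
        with pytest.raises(DuplicateChannelName):
            create_sample_from_matrix(np.ones((1, 2)), ["A", "A"])

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatch):
            create_sample_from_matrix(np.ones((1, 2)), ["A", "B", "C"])

    def test_matrix_fcs_roundtrip(self):
        rng = np.random.default_rng(5)
        mat = rng.uniform(0, 260000, (100, 3))
        s = create_sample_from_matrix(mat, ["A", "B", "C"])
        s2 = read_fcs(write_fcs(s, "raw"))
        assert np.allclose(s2.events_raw, mat, rtol=1e-6)


class TestSubsample:
    def test_full_and_empty(self, small_sample):
        assert len(subsample_events(small_sample, small_sample.n_events, 1)) == \
            small_sample.n_events
        assert len(subsample_events(small_sample, 0, 1)) == 0

    def test_deterministic_for_seed(self, small_sample):
        a = subsample_events(small_sample, 100, seed=42)
        b = subsample_events(small_sample, 100, seed=42)
        assert np.array_equal(a, b)
        assert len(np.unique(a)) == 100

    def test_too_large(self, small_sample):
        with pytest.raises(NTooLarge):
            subsample_events(small_sample, small_sample.n_events + 1, 0)
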