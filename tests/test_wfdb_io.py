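"""WFDB header/signal/annotation parsing and the CSV fixture dialect."""

import struct

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qrsbench as qb
from qrsbench.wfdb_io import (BEAT_CODES, UnsupportedFormatError, WfdbParseError,
                              _encode_annotations, _encode_fmt212,
                              write_annotations_csv)


def _write_wfdb(tmp_path, name, adc, gain=200, baseline=0, fs=360, fmt=212):
    """Hand-build a single-channel header + signal file from ADC integers."""
    hea = tmp_path / f"{name}.hea"
    hea.write_text(f"{name} 1 {fs} {len(adc)}\n"
                   f"{name}.dat {fmt} {gain}({baseline})/mV 12 {baseline} "
                   f"{adc[0]} 0 0 ECG\n")
    if fmt == 212:
        payload = _encode_fmt212(np.asarray(adc))
    else:
        payload = np.asarray(adc, dtype="<i2").tobytes()
    (tmp_path / f"{name}.dat").write_bytes(payload)
    return hea


class TestReadRecord:
    def test_format212_hand_decoded_block(self, tmp_path):
        """3-byte block for (+1, -1): b0=0x01, b1=0xF0, b2=0xFF -> ±0.005 mV."""
        hea = tmp_path / "x.hea"
        hea.write_text("x 1 360 2\nx.dat 212 200(0)/mV 12 0 1 0 0 ECG\n")
        (tmp_path / "x.dat").write_bytes(bytes([0x01, 0xF0, 0xFF]))
        rec = qb.read_record(hea)
        assert rec.fs == 360
        np.testing.assert_allclose(rec.samples, [+0.005, -0.005])

    def test_two_channel_interleaving_and_baseline(self, tmp_path):
        # frames (ch0, ch1): (1024+200, 1024-200) with gain 200, baseline 1024
        adc = [1224, 824, 1424, 624]
        hea = tmp_path / "r.hea"
        hea.write_text("r 2 360 2\n"
                       "r.dat 212 200(1024)/mV 12 1024 1224 0 0 MLII\n"
                       "r.dat 212 200(1024)/mV 12 1024 824 0 0 V5\n")
        (tmp_path / "r.dat").write_bytes(_encode_fmt212(np.asarray(adc)))
        upper = qb.read_record(hea, channel=0)
        lower = qb.read_record(hea, channel=1)
        np.testing.assert_allclose(upper.samples, [1.0, 2.0])
        np.testing.assert_allclose(lower.samples, [-1.0, -2.0])

    def test_format16(self, tmp_path):
        hea = _write_wfdb(tmp_path, "f16", [-500, 0, 500], fmt=16)
        rec = qb.read_record(hea)
        np.testing.assert_allclose(rec.samples, [-2.5, 0.0, 2.5])

    def test_unsupported_format_raises(self, tmp_path):
        hea = _write_wfdb(tmp_path, "bad", [0, 0])
        hea.write_text(hea.read_text().replace(" 212 ", " 80 "))
        with pytest.raises(UnsupportedFormatError):
            qb.read_record(hea)

    def test_corrupt_header_names_line(self, tmp_path):
        hea = tmp_path / "c.hea"
        hea.write_text("c 1 360\n")  # missing n_samples
        with pytest.raises(WfdbParseError, match="line 1"):
            qb.read_record(hea)

    def test_truncated_signal_raises(self, tmp_path):
        hea = _write_wfdb(tmp_path, "t", list(range(100)))
        (tmp_path / "t.dat").write_bytes(b"\x00" * 10)
        with pytest.raises(WfdbParseError, match="truncated"):
            qb.read_record(hea)

    def test_channel_out_of_range(self, tmp_path):
        hea = _write_wfdb(tmp_path, "one", [0, 1, 2])
        with pytest.raises(ValueError, match="channel"):
            qb.read_record(hea, channel=1)


class TestWriteRecord:
    def test_round_trip_within_one_adc_quantum(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = qb.EcgRecord("rt", 360.0, rng.normal(0, 1, 1000))
        back = qb.read_record(qb.write_record(rec, tmp_path / "rt.hea"))
        assert back.n_samples == 1000
        assert np.abs(back.samples - rec.samples).max() <= 1 / 200

    def test_constant_zero_decodes_to_baseline_exactly(self, tmp_path):
        rec = qb.EcgRecord("z", 360.0, np.zeros(11))
        back = qb.read_record(qb.write_record(rec, tmp_path / "z.hea"))
        assert np.all(back.samples == 0.0)

    def test_zero_length_rejected(self, tmp_path):
        rec = qb.EcgRecord("e", 360.0, np.empty(0))
        with pytest.raises(ValueError, match="zero-length"):
            qb.write_record(rec, tmp_path / "e.hea")

    def test_clipping_error_names_sample(self, tmp_path):
        samples = np.zeros(5)
        samples[3] = 100.0  # 20000 ADC units at gain 200: out of 12-bit range
        rec = qb.EcgRecord("clip", 360.0, samples)
        with pytest.raises(ValueError, match="sample 3"):
            qb.write_record(rec, tmp_path / "clip.hea")

    def test_csv_dialect_round_trip(self, tmp_path):
        rec = qb.EcgRecord("csvrec", 250.0, np.sin(np.arange(50) / 5))
        back = qb.read_record(qb.write_record(rec, tmp_path / "r.csv"))
        assert back.fs == 250.0
        assert back.record_id == "csvrec"
        np.testing.assert_allclose(back.samples, rec.samples, rtol=1e-6)

    @given(st.lists(st.integers(-2048, 2047), min_size=1, max_size=64))
    def test_format212_encode_decode_identity(self, adc):
        from qrsbench.wfdb_io import _decode_fmt212
        decoded = _decode_fmt212(_encode_fmt212(np.asarray(adc)), len(adc))
        assert decoded.tolist() == adc


class TestAnnotations:
    def test_hand_built_interval_stream(self, tmp_path):
        """Beats at 100 ('N', code 1) and 400 ('V', code 5), then EOF."""
        raw = struct.pack("<HHH", (1 << 10) | 100, (5 << 10) | 300, 0)
        path = tmp_path / "x.atr"
        path.write_bytes(raw)
        ann = qb.read_annotations(path)
        assert ann.entries == ((100, "N"), (400, "V"))
        assert ann.beat_only is False

    def test_skip_code_long_interval(self, tmp_path):
        # SKIP adds (hi<<16)|lo to the running time; next word adds its own interval
        raw = struct.pack("<HHHHH", (59 << 10), 1, 34464, (1 << 10) | 536, 0)
        path = tmp_path / "s.atr"
        path.write_bytes(raw)
        ann = qb.read_annotations(path)
        assert ann.entries == ((100000 + 536, "N"),)

    def test_empty_stream(self, tmp_path):
        path = tmp_path / "e.atr"
        path.write_bytes(struct.pack("<H", 0))
        assert len(qb.read_annotations(path)) == 0

    def test_truncated_stream_reports_offset(self, tmp_path):
        path = tmp_path / "t.atr"
        path.write_bytes(b"\x64")  # half a word
        with pytest.raises(WfdbParseError, match="byte 0"):
            qb.read_annotations(path)

    def test_unknown_code_raises(self, tmp_path):
        path = tmp_path / "u.atr"
        path.write_bytes(struct.pack("<HH", (50 << 10) | 3, 0))
        with pytest.raises(WfdbParseError, match="code 50"):
            qb.read_annotations(path)

    def test_reencoding_is_lossless_for_simple_streams(self, tmp_path):
        entries = ((10, "N"), (500, "V"), (900, "A"), (1500, "L"))
        raw = _encode_annotations(entries)
        path = tmp_path / "r.atr"
        path.write_bytes(raw)
        parsed = qb.read_annotations(path)
        assert parsed.entries == entries
        assert _encode_annotations(parsed.entries) == raw

    def test_csv_dialect(self, tmp_path):
        ann = qb.BeatAnnotations("a", ((5, "N"), (50, "+"), (99, "V")))
        back = qb.read_annotations(write_annotations_csv(ann, tmp_path / "a.csv"))
        assert back.entries == ann.entries


class TestFilterBeatAnnotations:
    @pytest.mark.parametrize("entries, expected", [
        (((10, "N"), (50, "+"), (90, "V")), ((10, "N"), (90, "V"))),
        (((10, "N"), (90, "V")), ((10, "N"), (90, "V"))),
        (((10, "~"), (20, "|")), ()),
    ])
    def test_examples(self, entries, expected):
        out = qb.filter_beat_annotations(qb.BeatAnnotations("x", entries))
        assert out.entries == expected
        assert out.beat_only is True

    def test_idempotent(self):
        ann = qb.BeatAnnotations("x", ((1, "N"), (300, "+"), (700, "f"), (999, '"')))
        once = qb.filter_beat_annotations(ann)
        assert qb.filter_beat_annotations(once).entries == once.entries

    def test_beat_code_set_is_the_standard_alphabet(self):
        assert BEAT_CODES == frozenset("NLRBAaJSVrFejnE/fQ?")


class TestInvariants:
    def test_annotation_indices_strictly_increasing_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            qb.BeatAnnotations("x", ((5, "N"), (5, "V")))

    def test_record_requires_finite_samples(self):
        with pytest.raises(ValueError, match="finite"):
            qb.EcgRecord("x", 360.0, np.array([0.0, np.nan]))

    def test_record_requires_positive_fs(self):
        with pytest.raises(ValueError, match="fs"):
            qb.EcgRecord("x", 0.0, np.zeros(3))
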