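"""Filtering, windowing, channel-to-lobe mapping, segment labeling, EDF I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epilobe import edf as edfio
from epilobe import preprocess as pp
from epilobe import synth
from epilobe.recording import Annotation, EEGRecording, map_channel_to_lobe


def _rec(data, rate=256.0, names=None):
    data = np.atleast_2d(data)
    names = names or [f"CH{i}" for i in range(data.shape[0])]
    return EEGRecording(data=data, sampling_rate=rate, channel_names=names)


class TestLowpass:
    def test_dc_passband_identity(self):
        rec = _rec(np.full((1, 1024), 7.5))
        out = pp.lowpass_filter(rec, 30.0)
        assert np.allclose(out.data, 7.5, atol=1e-9)

    def test_stopband_attenuation_at_45hz(self):
        t = np.arange(2048) / 256.0
        rec = _rec(np.sin(2 * np.pi * 45 * t))
        out = pp.lowpass_filter(rec, 30.0)
        # interior only: zero-phase filtering has edge transients
        atten_db = 20 * np.log10(np.abs(out.data[0, 512:-512]).max() / 1.0)
        assert atten_db <= -20.0

    def test_passband_gain_at_10hz(self):
        t = np.arange(2048) / 256.0
        rec = _rec(np.sin(2 * np.pi * 10 * t))
        out = pp.lowpass_filter(rec, 30.0)
        gain = np.abs(out.data[0, 256:-256]).max()
        assert abs(gain - 1.0) < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.lowpass_filter(_rec(np.zeros((1, 512))), cutoff=130.0)


class TestSegmentation:
    def test_two_second_windows_half_overlap(self):
        rec = _rec(np.zeros((2, 10 * 256)))
        segs = pp.segment_windows(rec, 2.0, 0.5)
        assert len(segs) == 9
        assert segs.starts == [i * 256 for i in range(9)]

    def test_non_overlapping_tiling(self):
        rec = _rec(np.zeros((1, 10 * 256)))
        assert len(pp.segment_windows(rec, 2.0, 0.0)) == 5

    def test_short_recording_empty_set(self):
        rec = _rec(np.zeros((1, 256)))
        assert len(pp.segment_windows(rec, 2.0, 0.5)) == 0

    @settings(max_examples=50, deadline=None)
    @given(
        n_s=st.integers(2, 40),
        window_s=st.sampled_from([1.0, 2.0, 4.0]),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    def test_count_matches_closed_form(self, n_s, window_s, overlap):
        rate = 64.0
        rec = _rec(np.zeros((1, int(n_s * rate))), rate=rate)
        segs = pp.segment_windows(rec, window_s, overlap)
        w = int(round(window_s * rate))
        h = max(1, int(round((1 - overlap) * w)))
        n = rec.n_samples
        expected = max(0, (n - w) // h + 1) if n >= w else 0
        assert len(segs) == expected


class TestLobeMapping:
    @pytest.mark.parametrize(
        "name,lobe",
        [
            ("F7-T7", "frontal"),
            ("FP1-F7", "frontal"),
            ("P7-O1", "parietal"),
            ("C3-P3", "excluded"),
            ("T8-P8", "temporal"),
            ("O1-A1", "occipital"),
            ("XX9", "excluded"),
        ],
    )
    def test_prefix_rule(self, name, lobe):
        assert map_channel_to_lobe(name) == lobe


class TestLabeling:
    def _segs(self, duration=60.0):
        rec = _rec(np.zeros((1, int(duration * 256))))
        return pp.segment_windows(rec, 2.0, 0.5)

    def test_window_inside_seizure(self):
        segs = pp.label_segments(self._segs(), [Annotation(10.0, 20.0)], 5.0)
        i = segs.starts.index(12 * 256)
        assert segs.labels[i] == "seizure"

    def test_window_far_from_seizure_is_interictal(self):
        segs = pp.label_segments(self._segs(), [Annotation(10.0, 20.0)], 5.0)
        i = segs.starts.index(40 * 256)
        assert segs.labels[i] == "non-seizure"

    def test_window_inside_margin_excluded(self):
        segs = pp.label_segments(self._segs(120.0), [Annotation(10.0, 20.0)], 60.0)
        i = segs.starts.index(50 * 256)  # 30 s after offset, margin 60 s
        assert segs.labels[i] == "excluded"

    def test_labeling_total_and_idempotent(self):
        anns = [Annotation(10.0, 20.0), Annotation(35.0, 40.0)]
        segs = pp.label_segments(self._segs(), anns, 5.0)
        first = list(segs.labels)
        assert all(l in ("seizure", "non-seizure", "excluded") for l in first)
        assert len(first) == len(segs)
        again = pp.label_segments(segs, anns, 5.0)
        assert again.labels == first

    def test_balance_within_one_segment(self):
        rec = _rec(np.zeros((1, int(200 * 256))))
        segs = pp.segment_windows(rec, 2.0, 0.5)
        segs = pp.label_segments(segs, [Annotation(60.0, 80.0)], 10.0)
        bal = pp.balance_segments(segs, ratio=1.0, seed=0)
        n_s = sum(1 for l in bal.labels if l == "seizure")
        n_n = sum(1 for l in bal.labels if l == "non-seizure")
        assert abs(n_s - n_n) <= 1
        assert "excluded" not in bal.labels


class TestEDF:
    def test_round_trip_within_quantization(self, tmp_path, frontal_recording):
        rec = frontal_recording.recording
        path = tmp_path / "subj.edf"
        edfio.write_edf(rec, path)
        edfio.write_annotations(rec.annotations, tmp_path / "subj.annotations.tsv")
        back = edfio.read_edf(path)
        assert back.channel_names == rec.channel_names
        assert back.sampling_rate == rec.sampling_rate
        span = rec.data.max() - rec.data.min()
        quant = span / 65535
        assert np.abs(back.data[:, : rec.n_samples] - rec.data).max() < 3 * quant
        assert len(back.annotations) == 1
        assert back.annotations[0].lobe == "frontal"

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            edfio.read_edf(tmp_path / "nope.edf")

    def test_malformed_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.edf"
        bad.write_bytes(b"this is not an EDF header")
        with pytest.raises(ValueError):
            edfio.read_edf(bad)

    def test_annotation_outside_duration_rejected(self, tmp_path):
        rec = EEGRecording(
            data=np.zeros((1, 512)), sampling_rate=256.0, channel_names=["FP1-F7"]
        )
        path = tmp_path / "s.edf"
        edfio.write_edf(rec, path)
        edfio.write_annotations(
            [Annotation(1.0, 99.0, "seizure")], tmp_path / "s.annotations.tsv"
        )
        with pytest.raises(ValueError):
            edfio.read_edf(path)
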