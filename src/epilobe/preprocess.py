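"""Preprocessing: low-pass filtering, DT-CWT denoising, windowing, labeling.

Windowing uses 0-based half-open sample intervals [start, start + w).
A segment is labeled `seizure` when at least `seizure_overlap` of its
samples fall inside an annotated seizure interval, `non-seizure` when it
lies wholly outside every interval padded by the temporal exclusion
margin, and `excluded` otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .dtcwt import denoise
from .recording import EEGRecording, map_channel_to_lobe  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentSet",
    "lowpass_filter",
    "denoise_recording",
    "segment_windows",
    "label_segments",
    "map_channel_to_lobe",
]


@dataclass
class SegmentSet:
    """Fixed-length windows cut from one recording."""

    segments: list  # list of channels x window_samples arrays
    window_s: float
    overlap: float
    sampling_rate: float
    starts: list = field(default_factory=list)  # sample index of each window
    labels: list = field(default_factory=list)  # 'seizure' | 'non-seizure' | 'excluded'
    lobes: list = field(default_factory=list)  # lobe name or None per segment
    levels: list = field(default_factory=list)  # activity tier or None per segment
    source_subject: str = "S000"
    partition: str = "train"

    def __len__(self):
        return len(self.segments)

    @property
    def window_samples(self):
        return int(round(self.window_s * self.sampling_rate))

    def select(self, indices):
        """New SegmentSet restricted to `indices` (labels etc. follow)."""
        pick = lambda xs: [xs[i] for i in indices] if xs else []
        return SegmentSet(
            segments=pick(self.segments),
            window_s=self.window_s,
            overlap=self.overlap,
            sampling_rate=self.sampling_rate,
            starts=pick(self.starts),
            labels=pick(self.labels),
            lobes=pick(self.lobes),
            levels=pick(self.levels),
            source_subject=self.source_subject,
            partition=self.partition,
        )


def lowpass_filter(rec, cutoff=30.0, order=4):
    """Zero-phase Butterworth low-pass per channel; length preserved."""
    nyquist = rec.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz")
    sos = sps.butter(order, cutoff, btype="low", fs=rec.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy(data=filtered)


def denoise_recording(rec, levels=4, threshold_rule="universal"):
    """DT-CWT denoising applied channel by channel."""
    out = np.vstack(
        [denoise(rec.data[ch], levels=levels, threshold_rule=threshold_rule) for ch in range(rec.n_channels)]
    )
    return rec.copy(data=out)


def segment_windows(rec, window_s=2.0, overlap=0.5):
    """Sliding windows with hop = (1 - overlap) * window; the trailing
    partial window is dropped.  Count = floor((N - w) / h) + 1."""
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    w = int(round(window_s * rec.sampling_rate))
    h = max(1, int(round((1.0 - overlap) * w)))
    n = rec.n_samples
    segs = SegmentSet(
        segments=[],
        window_s=window_s,
        overlap=overlap,
        sampling_rate=rec.sampling_rate,
        source_subject=rec.subject,
    )
    if n < w:
        logger.warning(
            "recording %s shorter than one %gs window; empty segment set", rec.subject, window_s
        )
        return segs
    for start in range(0, n - w + 1, h):
        segs.segments.append(rec.data[:, start : start + w])
        segs.starts.append(start)
    return segs


def label_segments(segs, annotations, exclusion_margin_s=60.0, seizure_overlap=0.5):
    """Assign exactly one of {seizure, non-seizure, excluded} per segment.

    Labeling is idempotent (it rewrites the label lists) and total.
    The lobe and activity tier of the covering annotation are carried
    onto seizure segments.
    """
    rate = segs.sampling_rate
    w = segs.window_samples
    intervals = [(a.onset * rate, a.offset * rate, a) for a in annotations]
    margin = exclusion_margin_s * rate
    segs.labels, segs.lobes, segs.levels = [], [], []
    for start in segs.starts:
        end = start + w
        overlap_best, ann_best = 0.0, None
        near = False
        for (i0, i1, a) in intervals:
            ov = max(0.0, min(end, i1) - max(start, i0))
            if ov > overlap_best:
                overlap_best, ann_best = ov, a
            if max(start, i0 - margin) < min(end, i1 + margin):
                near = True
        if overlap_best >= seizure_overlap * w:
            segs.labels.append("seizure")
            segs.lobes.append(getattr(ann_best, "lobe", None))
            segs.levels.append(getattr(ann_best, "level", None))
        elif not near:
            segs.labels.append("non-seizure")
            segs.lobes.append(None)
            segs.levels.append(None)
        else:
            segs.labels.append("excluded")
            segs.lobes.append(None)
            segs.levels.append(None)
    return segs


def balance_segments(segs, ratio=1.0, seed=0):
    """Subsample the majority class toward `ratio` = seizure / non-seizure
    (within one segment); excluded segments are dropped."""
    idx_seiz = [i for i, l in enumerate(segs.labels) if l == "seizure"]
    idx_non = [i for i, l in enumerate(segs.labels) if l == "non-seizure"]
    rng = np.random.default_rng(seed)
    if idx_seiz and idx_non:
        want_non = int(round(len(idx_seiz) / ratio))
        if len(idx_non) > want_non:
            idx_non = sorted(rng.choice(idx_non, size=want_non, replace=False))
        else:
            want_seiz = int(round(len(idx_non) * ratio))
            if len(idx_seiz) > want_seiz:
                idx_seiz = sorted(rng.choice(idx_seiz, size=want_seiz, replace=False))
    return segs.select(sorted(idx_seiz + idx_non))
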