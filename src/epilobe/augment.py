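"""Training-set-only signal augmentation.

Six length-preserving transforms on channels x samples segments:
noise injection (to a target SNR), polarity inversion, circular time
shifting, time stretching, pitch scaling (spectral resampling), and
random gain.  Augmentation is refused outright on validation/test
partitions — the leakage guard is a hard error, not a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = ["AugmentSpec", "LeakageError", "augment_signal", "augment_segments", "TRANSFORMS"]

TRANSFORMS = (
    "noise_injection",
    "polarity_inversion",
    "time_shift",
    "time_stretch",
    "pitch_scale",
    "random_gain",
)

#: default parameter ranges used when sampling random augmentations
DEFAULT_RANGES = {
    "noise_injection": (5.0, 20.0),  # target SNR, dB
    "time_shift": (-0.25, 0.25),  # seconds
    "time_stretch": (0.9, 1.1),  # stretch factor
    "pitch_scale": (-2.0, 2.0),  # semitones
    "random_gain": (-6.0, 6.0),  # dB
}


class LeakageError(RuntimeError):
    """Raised when augmentation is requested on a validation/test partition."""


@dataclass
class AugmentSpec:
    transform: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


def _fit_length(x, n):
    if x.shape[-1] >= n:
        return x[..., :n]
    pad = np.zeros(x.shape[:-1] + (n - x.shape[-1],))
    return np.concatenate([x, pad], axis=-1)


def augment_signal(segment, spec, sampling_rate=256.0):
    """Apply one augmentation to a channels x samples segment."""
    x = np.atleast_2d(np.asarray(segment, dtype=float))
    n = x.shape[-1]
    if n == 0:
        raise ValueError("empty segment")
    rng = np.random.default_rng(spec.seed)
    t = spec.transform
    p = spec.params
    if t == "noise_injection":
        target_db = float(p.get("snr_db", 10.0))
        noise = rng.standard_normal(x.shape)
        ps = np.sum(x**2)
        pn = np.sum(noise**2)
        if ps > 0 and pn > 0:
            noise *= np.sqrt(ps / (pn * 10 ** (target_db / 10.0)))
        return x + noise
    if t == "polarity_inversion":
        return -x
    if t == "time_shift":
        shift = int(round(float(p.get("shift_s", 0.0)) * sampling_rate))
        return np.roll(x, shift, axis=-1)
    if t == "time_stretch":
        factor = float(p.get("factor", 1.0))
        if factor == 1.0:
            return x.copy()
        m = max(2, int(round(n * factor)))
        y = sps.resample(x, m, axis=-1)
        return _fit_length(y, n)
    if t == "pitch_scale":
        semitones = float(p.get("semitones", 0.0))
        r = 2.0 ** (semitones / 12.0)
        if r == 1.0:
            return x.copy()
        # rate-preserving frequency scaling: resample, keep original length
        m = max(2, int(round(n / r)))
        y = sps.resample(x, m, axis=-1)
        return _fit_length(y, n)
    if t == "random_gain":
        gain_db = float(p.get("gain_db", 0.0))
        return x * 10 ** (gain_db / 20.0)
    raise ValueError(f"unknown transform {t!r}")  # pragma: no cover


def sample_spec(rng):
    """Draw a random AugmentSpec from the default ranges."""
    t = TRANSFORMS[int(rng.integers(len(TRANSFORMS)))]
    lo_hi = DEFAULT_RANGES.get(t)
    params = {}
    if t == "noise_injection":
        params["snr_db"] = float(rng.uniform(*lo_hi))
    elif t == "time_shift":
        params["shift_s"] = float(rng.uniform(*lo_hi))
    elif t == "time_stretch":
        params["factor"] = float(rng.uniform(*lo_hi))
    elif t == "pitch_scale":
        params["semitones"] = float(rng.uniform(*lo_hi))
    elif t == "random_gain":
        params["gain_db"] = float(rng.uniform(*lo_hi))
    return AugmentSpec(transform=t, params=params, seed=int(rng.integers(2**31 - 1)))


def augment_segments(segs, multiplicity=1, seed=0):
    """Append `multiplicity` random augmented copies of every segment.

    Hard-fails on validation/test partitions (leakage guard).
    Returns (segments, labels, lobes, levels) lists including originals.
    """
    if segs.partition != "train":
        raise LeakageError(
            f"augmentation requested on partition {segs.partition!r}; "
            "only the training set may be augmented"
        )
    rng = np.random.default_rng(seed)
    out_x = list(segs.segments)
    out_y = list(segs.labels)
    out_lobe = list(segs.lobes)
    out_level = list(segs.levels)
    for i, seg in enumerate(segs.segments):
        for _ in range(multiplicity):
            spec = sample_spec(rng)
            out_x.append(augment_signal(seg, spec, sampling_rate=segs.sampling_rate))
            out_y.append(segs.labels[i])
            out_lobe.append(segs.lobes[i])
            out_level.append(segs.levels[i])
    return out_x, out_y, out_lobe, out_level
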