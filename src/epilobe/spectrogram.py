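"""STFT spectrograms for the backbone.

Per channel: magnitude STFT with a 256-sample Hamming window, 256-point
FFT, and hop 128 (50% overlap); frames are taken without centering or
padding so the frame count is exactly floor((N - 256) / 128) + 1.  The
rows are cropped to 0-30 Hz, channels are averaged into one composite
image, log-scaled, min-max normalized to [0, 1], and bilinearly resized
to the model input shape (224 x 224 x 1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft
from scipy.signal import get_window
from skimage.transform import resize

__all__ = ["StftParams", "Spectrogram", "stft_magnitude", "spectrogram"]


@dataclass
class StftParams:
    window: int = 256
    n_fft: int = 256
    hop: int = 128
    fmax: float = 30.0
    out_shape: tuple = (224, 224)
    eps: float = 1e-10


@dataclass
class Spectrogram:
    values: np.ndarray  # height x width x 1 in [0, 1]
    params: StftParams

    @property
    def shape(self):
        return self.values.shape


def stft_magnitude(x, params=None):
    """Magnitude STFT (freq bins x frames) of a 1-D signal, no padding."""
    p = params or StftParams()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < p.window:
        raise ValueError(f"segment of {n} samples shorter than the {p.window}-sample window")
    n_frames = (n - p.window) // p.hop + 1
    idx = np.arange(p.window)[None, :] + p.hop * np.arange(n_frames)[:, None]
    frames = x[idx] * get_window("hamming", p.window, fftbins=True)
    return np.abs(spfft.rfft(frames, n=p.n_fft, axis=1)).T


def spectrogram(segment, sampling_rate=256.0, params=None):
    """Composite multi-channel spectrogram image for one segment."""
    p = params or StftParams()
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    mags = [stft_magnitude(seg[ch], p) for ch in range(seg.shape[0])]
    mag = np.mean(mags, axis=0)
    freqs = np.arange(p.n_fft // 2 + 1) * sampling_rate / p.n_fft
    mag = mag[freqs <= p.fmax + 1e-9, :]
    img = np.log(mag + p.eps)
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    img = resize(img, p.out_shape, order=1, mode="edge", anti_aliasing=False)
    return Spectrogram(values=img[:, :, None].astype(np.float32), params=p)
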