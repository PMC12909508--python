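"""Dual-tree complex wavelet transform (1-D) and wavelet denoising.

The transform runs two parallel real DWTs: tree *a* gives the real part
and tree *b* the imaginary part of each complex sub-band.  Approximate
analyticity comes from a half-sample delay between the trees, obtained
here with linear-phase biorthogonal filter pairs of odd length (integer
group delay, tree *a*) and even length (half-integer group delay, tree
*b*); at the first level both trees share one filter and tree *b* sees
the input delayed by one sample.  Each tree is a perfectly
reconstructing periodized filter bank, so the round trip with untouched
coefficients is exact to floating-point precision.

Denoising soft-thresholds the *magnitude* of the complex detail
coefficients (the approximation band is never touched) and averages the
two trees' reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "DTCWTCoefficients",
    "dtcwt_decompose",
    "dtcwt_reconstruct",
    "denoise",
]

#: level-1 filter shared by both trees (tree b input delayed one sample)
LEVEL1_WAVELET = "bior4.4"
#: odd-length linear-phase pair -> integer group delay (tree a, levels >= 2)
TREE_A_WAVELET = "bior4.4"
#: even-length linear-phase pair -> half-sample group delay (tree b, levels >= 2)
TREE_B_WAVELET = "bior3.5"

_MODE = "periodization"


@dataclass
class DTCWTCoefficients:
    """Complex sub-bands of a four-level dual-tree decomposition.

    ``details[k]`` holds D_{k+1} = D_real + i·D_imag; ``approximation``
    holds the deepest complex approximation band (A4 by default).
    """

    details: list  # complex arrays, finest first (D1 .. Dlevels)
    approximation: np.ndarray  # complex array
    length: int
    filter_bank_id: str = field(
        default=f"level1={LEVEL1_WAVELET};treeA={TREE_A_WAVELET};treeB={TREE_B_WAVELET}"
    )

    @property
    def levels(self):
        return len(self.details)


def _tree_decompose(x, levels, shift):
    """One real DWT tree; `shift` delays the input by one sample (tree b)."""
    a = np.roll(x, shift) if shift else np.asarray(x, dtype=float)
    details = []
    for lev in range(levels):
        wav = LEVEL1_WAVELET if lev == 0 else (TREE_B_WAVELET if shift else TREE_A_WAVELET)
        a, d = pywt.dwt(a, wav, mode=_MODE)
        details.append(d)
    return details, a


def _tree_reconstruct(details, approx, length, shift):
    a = approx
    for lev in reversed(range(len(details))):
        wav = LEVEL1_WAVELET if lev == 0 else (TREE_B_WAVELET if shift else TREE_A_WAVELET)
        d = details[lev]
        if len(a) > len(d):  # periodization keeps ceil(n/2); trim if uneven
            a = a[: len(d)]
        a = pywt.idwt(a, d, wav, mode=_MODE)
    a = a[:length]
    return np.roll(a, -shift) if shift else a


def dtcwt_decompose(signal, levels=4):
    """Decompose a 1-D signal into `levels` complex detail sub-bands + approximation."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("dtcwt_decompose expects a 1-D signal")
    if len(x) < 2**levels:
        raise ValueError(f"signal of length {len(x)} too short for {levels} levels")
    da, aa = _tree_decompose(x, levels, shift=0)
    db, ab = _tree_decompose(x, levels, shift=1)
    details = [ra + 1j * rb for ra, rb in zip(da, db)]
    return DTCWTCoefficients(details=details, approximation=aa + 1j * ab, length=len(x))


def dtcwt_reconstruct(coeffs):
    """Inverse transform: average of the two trees' exact reconstructions."""
    da = [d.real for d in coeffs.details]
    db = [d.imag for d in coeffs.details]
    xa = _tree_reconstruct(da, coeffs.approximation.real, coeffs.length, shift=0)
    xb = _tree_reconstruct(db, coeffs.approximation.imag, coeffs.length, shift=1)
    return 0.5 * (xa + xb)


def _universal_threshold(d):
    """Per-sub-band universal threshold from a robust noise estimate.

    sigma is the median absolute deviation of the complex magnitudes
    around their median, scaled for Gaussian consistency.
    """
    mag = np.abs(d)
    sigma = np.median(np.abs(mag - np.median(mag))) / 0.6745
    return sigma * np.sqrt(2.0 * np.log(max(len(d), 2)))


def denoise(signal, levels=4, threshold_rule="universal", threshold=None):
    """DT-CWT denoising: soft-threshold complex detail magnitudes, reconstruct.

    Parameters
    ----------
    signal : 1-D array
    levels : decomposition depth (default 4)
    threshold_rule : 'universal' (per-sub-band MAD estimate) or 'fixed'
    threshold : scalar used when ``threshold_rule == 'fixed'``

    ``threshold = 0`` with the 'fixed' rule reproduces the input up to
    floating-point error (perfect reconstruction).
    """
    coeffs = dtcwt_decompose(signal, levels=levels)
    for k, d in enumerate(coeffs.details):
        if threshold_rule == "fixed":
            t = float(threshold or 0.0)
        elif threshold_rule == "universal":
            t = _universal_threshold(d)
        else:
            raise ValueError(f"unknown threshold rule: {threshold_rule!r}")
        if t > 0:
            mag = np.abs(d)
            shrink = np.maximum(mag - t, 0.0) / np.maximum(mag, 1e-30)
            coeffs.details[k] = d * shrink
    return dtcwt_reconstruct(coeffs)
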