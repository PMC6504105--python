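"""Single-level undecimated 3D wavelet decomposition.

Applies a low- (L) or high-pass (H) filter along each of the three axes
in all 8 combinations, yielding 8 subbands the same size as the input
(undecimated, so every subband stays aligned with the tumor mask).
Filters come from PyWavelets (default Haar) and are rescaled by 1/sqrt(2)
per axis so that, with circular boundary handling, an orthonormal kernel
partitions the input energy exactly across the 8 subbands.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import convolve1d

from .catalog import WAVELET_SUBBANDS


def wavelet_subbands(image: np.ndarray, wavelet: str = "haar") -> dict[str, np.ndarray]:
    """Decompose a 3D image into the 8 LLL..HHH subbands.

    Returns a dict keyed by subband label (lexicographic {L,H}^3 order,
    letter k = filter on axis k); each subband has the input's shape.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3:
        raise ValueError("expected a 3D image")
    if any(s < 2 for s in img.shape):
        raise ValueError("each axis needs at least 2 voxels")
    w = pywt.Wavelet(wavelet)
    lo = np.asarray(w.dec_lo, dtype=float) / np.sqrt(2.0)
    hi = np.asarray(w.dec_hi, dtype=float) / np.sqrt(2.0)
    bank = {"L": lo, "H": hi}
    out: dict[str, np.ndarray] = {}
    for label in WAVELET_SUBBANDS:
        sub = img
        for axis, letter in enumerate(label):
            sub = convolve1d(sub, bank[letter], axis=axis, mode="wrap")
        out[label] = sub
    return out
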