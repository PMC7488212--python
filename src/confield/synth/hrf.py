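"""Canonical double-gamma hemodynamic response and convolution helper."""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import gamma as _gamma

HRF_PEAK_S = 6.0
HRF_UNDERSHOOT_S = 16.0
HRF_RATIO = 1.0 / 6.0
HRF_LENGTH_S = 32.0


def double_gamma_hrf(
    t: np.ndarray,
    peak_s: float = HRF_PEAK_S,
    undershoot_s: float = HRF_UNDERSHOOT_S,
    ratio: float = HRF_RATIO,
) -> np.ndarray:
    """Difference of two gamma densities (shape = peak/undershoot,
    unit scale), normalized to unit peak."""
    h = _gamma.pdf(t, peak_s) - ratio * _gamma.pdf(t, undershoot_s)
    peak = h.max()
    return h / peak if peak > 0 else h


def convolve_hrf(
    neural: np.ndarray,
    tr_s: float,
    *,
    peak_s: float = HRF_PEAK_S,
    undershoot_s: float = HRF_UNDERSHOOT_S,
    ratio: float = HRF_RATIO,
) -> np.ndarray:
    """Causal convolution of (T, n) neural series with the HRF at TR
    resolution; output keeps the input length."""
    t = np.arange(0.0, HRF_LENGTH_S + tr_s, tr_s)
    kernel = double_gamma_hrf(t, peak_s, undershoot_s, ratio)
    out = fftconvolve(neural, kernel[:, None], axes=0)
    return out[: neural.shape[0]]
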