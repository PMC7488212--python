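"""Condition-specific temporal filtering of BOLD series.

Stimulus runs get only linear detrending (band-pass filtering would
remove the slow stimulus-locked signal); resting runs get a zero-phase
0.01-0.1 Hz band-pass after detrending.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import detrend as _sp_detrend

from .types import TimeSeriesMatrix

BAND_LO_HZ = 0.01
BAND_HI_HZ = 0.1
TRANSITION_HZ = 0.005


def detrend_linear(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Remove each unit's least-squares line (intercept + slope).

    Output columns have zero mean and zero linear trend to machine
    precision; the operation is linear and idempotent.
    """
    if ts.values.shape[0] < 3:
        raise ValueError(f"need >= 3 volumes to detrend, got {ts.values.shape[0]}")
    out = _sp_detrend(ts.values, axis=0, type="linear")
    return ts.with_values(out)


def _bandpass_mask(freqs: np.ndarray, f_lo: float, f_hi: float, tw: float) -> np.ndarray:
    """Raised-cosine band mask: 1 on [f_lo, f_hi], cosine ramps of width tw."""
    m = np.zeros_like(freqs)
    inside = (freqs >= f_lo) & (freqs <= f_hi)
    m[inside] = 1.0
    lo_ramp = (freqs > f_lo - tw) & (freqs < f_lo)
    m[lo_ramp] = 0.5 * (1 - np.cos(np.pi * (freqs[lo_ramp] - (f_lo - tw)) / tw))
    hi_ramp = (freqs > f_hi) & (freqs < f_hi + tw)
    m[hi_ramp] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_ramp] - f_hi) / tw))
    m[freqs == 0.0] = 0.0  # DC always removed
    return m


def bandpass(
    ts: TimeSeriesMatrix,
    f_lo: float = BAND_LO_HZ,
    f_hi: float = BAND_HI_HZ,
    transition_hz: float = TRANSITION_HZ,
) -> TimeSeriesMatrix:
    """Zero-phase band-pass via a frequency-domain raised-cosine mask.

    Components with frequency strictly inside (f_lo, f_hi) are preserved;
    components more than one transition width outside the band are fully
    attenuated. DC is removed unconditionally.
    """
    nyquist = 1.0 / (2.0 * ts.tr_s)
    if not (0.0 < f_lo < f_hi < nyquist):
        raise ValueError(
            f"band ({f_lo}, {f_hi}) Hz incompatible with TR {ts.tr_s} s "
            f"(Nyquist = {nyquist:.4g} Hz); need 0 < f_lo < f_hi < Nyquist"
        )
    n = ts.values.shape[0]
    spec = np.fft.rfft(ts.values, axis=0)
    freqs = np.fft.rfftfreq(n, d=ts.tr_s)
    spec *= _bandpass_mask(freqs, f_lo, f_hi, transition_hz)[:, None]
    out = np.fft.irfft(spec, n=n, axis=0)
    return ts.with_values(out)


def preprocess_run(ts: TimeSeriesMatrix, **band_kwargs) -> TimeSeriesMatrix:
    """Dispatch on the condition tag: stimulus -> detrend only;
    rest -> detrend then band-pass."""
    if ts.condition == "stimulus":
        return detrend_linear(ts)
    if ts.condition == "rest":
        return bandpass(detrend_linear(ts), **band_kwargs)
    raise ValueError(f"unknown condition tag {ts.condition!r}")
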