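"""Spectral HRV: LF and HF band powers of the RR tachogram and their ratio.

The irregularly sampled tachogram (RR value at each beat onset) is resampled
to an even grid by cubic interpolation, mean-removed, and its power spectral
density estimated with a Welch averaged periodogram (Hann taper, 120-s
windows, 50% overlap by default).  Band powers are trapezoidal integrals
over LF = [0.04, 0.15) Hz and HF = [0.15, 0.4) Hz (half-open so 0.15 Hz is
never counted twice).  A Lomb-Scargle estimator on the raw beat times is
available as an alternative; absolute band powers are estimator-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

MIN_SPAN_S = 60.0
MIN_BEATS = 30


@dataclass
class BandPowers:
    lf_power: float  # ms^2
    hf_power: float  # ms^2

    @property
    def lf_hf(self) -> float:
        if self.hf_power > 0:
            return self.lf_power / self.hf_power
        return float("nan")


def band_powers(
    intervals_ms,
    onset_times_s,
    method: str = "welch",
    resample_hz: float = 4.0,
    welch_window_s: float = 120.0,
) -> BandPowers:
    """LF/HF band powers of one segment's tachogram.

    Parameters
    ----------
    intervals_ms, onset_times_s : array-like
        RR values (ms) and the onset time (s) of each interval.
    method : {"welch", "lombscargle"}
    """
    x = np.asarray(intervals_ms, dtype=float)
    t = np.asarray(onset_times_s, dtype=float)
    if len(x) != len(t):
        raise InsufficientDataError("intervals and times differ in length")
    if len(x) < MIN_BEATS or (len(t) and t[-1] - t[0] < MIN_SPAN_S):
        raise InsufficientDataError(
            f"spectral analysis needs >= {MIN_BEATS} beats over >= {MIN_SPAN_S:g} s"
        )
    if method == "welch":
        f, pxx = _welch_psd(x, t, resample_hz, welch_window_s)
    elif method == "lombscargle":
        f, pxx = _lomb_psd(x, t)
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    return BandPowers(
        lf_power=_band_integral(f, pxx, *LF_BAND),
        hf_power=_band_integral(f, pxx, *HF_BAND),
    )


def _welch_psd(x, t, resample_hz, welch_window_s):
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    resampled = CubicSpline(t, x)(grid)
    resampled = resampled - resampled.mean()
    nperseg = min(len(grid), int(welch_window_s * resample_hz))
    f, pxx = signal.welch(
        resampled,
        fs=resample_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
    )
    return f, pxx


def _lomb_psd(x, t):
    # PSD-normalized Lomb-Scargle on the raw (irregular) beat times.
    f = np.arange(0.005, 0.5, 0.005)
    xc = x - x.mean()
    pgram = signal.lombscargle(t, xc, 2 * np.pi * f)
    # normalize so the integral equals the series variance (Parseval-style);
    # this fixes an absolute scale while preserving band ratios.
    var = float(np.var(xc))
    total = np.trapezoid(pgram, f)
    pxx = pgram * (var / total) if total > 0 else pgram
    return f, pxx


def _band_integral(f: np.ndarray, pxx: np.ndarray, lo: float, hi: float) -> float:
    mask = (f >= lo) & (f < hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(pxx[mask], f[mask]))
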