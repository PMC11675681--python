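"""Symmetric time-domain HRV descriptors.

The Poincaré plot of an RR series is the scatter of consecutive pairs
(x_i, x_{i+1}).  For each point we use two signed coordinates:

    d_i = (x_{i+1} - x_i) / sqrt(2)          distance from the identity line
    s_i = (x_i + x_{i+1} - 2*xbar) / sqrt(2)  position along the identity line

with xbar the mean over all plot coordinates.  SD1 and SD2 are the root
second moments of d and s (divisor N = number of points, not re-centred);
under this convention the deceleration/acceleration variance partitions of
the asymmetry module close exactly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import InsufficientDataError

PNN_THRESHOLD_MS = 30.0


def _as_pieces(rr) -> list[np.ndarray]:
    """Normalize input to a list of 1-d arrays (pieces never bridge edits)."""
    if isinstance(rr, (list, tuple)) and rr and not np.isscalar(rr[0]):
        return [np.asarray(p, dtype=float) for p in rr]
    return [np.asarray(rr, dtype=float)]


def successive_differences(rr) -> np.ndarray:
    """Pooled x_{i+1} - x_i over the pieces of a series (ms)."""
    pieces = [p for p in _as_pieces(rr) if len(p) >= 2]
    if not pieces:
        raise InsufficientDataError("need at least 2 intervals")
    return np.concatenate([np.diff(p) for p in pieces])


def poincare_points(rr) -> tuple[np.ndarray, np.ndarray]:
    """Signed Poincaré coordinates (d, s) pooled over pieces."""
    pieces = [p for p in _as_pieces(rr) if len(p) >= 2]
    if not pieces:
        raise InsufficientDataError("need at least 2 intervals for Poincaré pairs")
    x = np.concatenate([p[:-1] for p in pieces])
    y = np.concatenate([p[1:] for p in pieces])
    xbar = (x.sum() + y.sum()) / (2 * len(x))
    d = (y - x) / np.sqrt(2.0)
    s = (x + y - 2.0 * xbar) / np.sqrt(2.0)
    return d, s


def sdnn(rr, ddof: int = 1) -> float:
    """Standard deviation of (normal-to-normal) intervals, ms.

    Default is the sample SD (divisor n-1); ``ddof=0`` gives the population
    form.
    """
    x = np.concatenate(_as_pieces(rr))
    if len(x) < 2:
        raise InsufficientDataError("sdnn needs at least 2 intervals")
    return float(np.std(x, ddof=ddof))


def sd1(rr) -> float:
    """Short-term variability: root mean square distance from the identity line."""
    d, _ = _points_checked(rr)
    return float(np.sqrt(np.mean(d**2)))


def sd2(rr) -> float:
    """Long-term variability: root mean square position along the identity line."""
    _, s = _points_checked(rr)
    return float(np.sqrt(np.mean(s**2)))


def _points_checked(rr):
    d, s = poincare_points(rr)
    if len(d) < 2:
        raise InsufficientDataError("SD1/SD2 need at least 3 intervals")
    return d, s


def pnn30(rr, threshold_ms: float = PNN_THRESHOLD_MS) -> float:
    """Percent of successive differences with |delta| strictly above 30 ms.

    Computed as the sum of the two directional percentages so that
    pnn30 == pnn30dec + pnn30acc holds exactly in floating point.
    """
    dx = successive_differences(rr)
    n = len(dx)
    return float(100.0 * np.sum(dx > threshold_ms) / n) + float(
        100.0 * np.sum(dx < -threshold_ms) / n
    )
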