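"""Heart-rate-asymmetry descriptors.

A deceleration is a lengthening of the RR interval (the heart slows down),
an acceleration a shortening.  Three families of descriptors are computed:

* variance-based: the short-term, long-term and total Poincaré variances are
  split into deceleration and acceleration parts,

      SD1^2  = SD1d^2  + SD1a^2
      SD2^2  = SD2d^2  + SD2a^2
      SDNN^2 = SDNNd^2 + SDNNa^2   (plot-based SDNN^2 = (SD1^2 + SD2^2)/2)

  where points on the identity line (no change) contribute half of their
  along-line second moment to each side so the partitions close exactly;

* runs-based: maximal blocks of consecutive monotone changes. DRi / ARi
  count deceleration / acceleration runs of length i, DRMAX / ARMAX are the
  longest such runs, and the Shannon entropy of the run-type/length
  distribution splits into a deceleration part HDR and an acceleration part
  HAR;

* threshold-based: pNN30dec / pNN30acc, the percentages of successive
  differences above +30 ms / below -30 ms, which sum exactly to pNN30.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .hrv_time import (
    PNN_THRESHOLD_MS,
    _as_pieces,
    poincare_points,
    successive_differences,
)


@dataclass
class VarianceDecomposition:
    sd1d: float
    sd1a: float
    sd2d: float
    sd2a: float
    sdnnd: float
    sdnna: float


@dataclass
class RunsDistribution:
    dr_counts: dict[int, int]
    ar_counts: dict[int, int]
    neutral_counts: dict[int, int]

    @property
    def dr_max(self) -> int:
        return max(self.dr_counts, default=0)

    @property
    def ar_max(self) -> int:
        return max(self.ar_counts, default=0)

    @property
    def n_runs(self) -> int:
        return (
            sum(self.dr_counts.values())
            + sum(self.ar_counts.values())
            + sum(self.neutral_counts.values())
        )


@dataclass
class RunsEntropy:
    hdr: float
    har: float
    h_total: float


@dataclass
class ThresholdCounts:
    pnn30dec: float
    pnn30acc: float


def classify_deltas(rr) -> np.ndarray:
    """Sign of each successive difference: +1 dec, -1 acc, 0 neutral."""
    return np.sign(successive_differences(rr)).astype(int)


def variance_decomposition(rr) -> VarianceDecomposition:
    """Split SD1^2, SD2^2 and plot-based SDNN^2 by change direction."""
    d, s = poincare_points(rr)
    if len(d) < 2:
        raise InsufficientDataError("variance decomposition needs >= 3 intervals")
    n = len(d)
    dec, acc, neu = d > 0, d < 0, d == 0
    sd1d2 = float(np.sum(d[dec] ** 2) / n)
    sd1a2 = float(np.sum(d[acc] ** 2) / n)
    sd2d2 = float((np.sum(s[dec] ** 2) + 0.5 * np.sum(s[neu] ** 2)) / n)
    sd2a2 = float((np.sum(s[acc] ** 2) + 0.5 * np.sum(s[neu] ** 2)) / n)
    sdnnd2 = (sd1d2 + sd2d2) / 2.0
    sdnna2 = (sd1a2 + sd2a2) / 2.0
    return VarianceDecomposition(
        sd1d=np.sqrt(sd1d2),
        sd1a=np.sqrt(sd1a2),
        sd2d=np.sqrt(sd2d2),
        sd2a=np.sqrt(sd2a2),
        sdnnd=np.sqrt(sdnnd2),
        sdnna=np.sqrt(sdnna2),
    )


def runs_partition(rr) -> RunsDistribution:
    """Counts of maximal monotone runs by type and length.

    Run length is the number of successive-difference terms in the block, so
    the lengths of all runs sum to n-1 for an unbroken n-beat series.  When
    the input is split into pieces, runs never bridge a piece boundary.
    """
    dr: dict[int, int] = {}
    ar: dict[int, int] = {}
    ne: dict[int, int] = {}
    pieces = [p for p in _as_pieces(rr) if len(p) >= 2]
    if not pieces:
        raise InsufficientDataError("runs need at least 2 intervals")
    for piece in pieces:
        signs = np.sign(np.diff(piece)).astype(int)
        boundaries = np.flatnonzero(np.diff(signs) != 0) + 1
        for block in np.split(signs, boundaries):
            length = len(block)
            target = dr if block[0] > 0 else ar if block[0] < 0 else ne
            target[length] = target.get(length, 0) + 1
    return RunsDistribution(dr, ar, ne)


def runs_entropy(
    dist: RunsDistribution, base: float = 2.0, include_neutral: bool = True
) -> RunsEntropy:
    """Shannon entropy of the run-type/length distribution, partitioned.

    Each (type, length) bin has probability count / R with R the total number
    of runs (neutral runs included in R by default).  HDR sums the -p*log(p)
    terms of deceleration bins, HAR those of acceleration bins; the total
    adds the neutral terms.
    """
    groups = [dist.dr_counts, dist.ar_counts]
    if include_neutral:
        r_total = dist.n_runs
        groups.append(dist.neutral_counts)
    else:
        r_total = sum(dist.dr_counts.values()) + sum(dist.ar_counts.values())
    if r_total == 0:
        raise InsufficientDataError("empty runs distribution")

    def _part(counts: dict[int, int]) -> float:
        p = np.array([c / r_total for c in counts.values() if c > 0])
        if len(p) == 0:
            return 0.0
        return float(-(p * np.log(p) / np.log(base)).sum())

    hdr = _part(dist.dr_counts)
    har = _part(dist.ar_counts)
    h_total = hdr + har + (_part(dist.neutral_counts) if include_neutral else 0.0)
    return RunsEntropy(hdr=hdr, har=har, h_total=h_total)


def threshold_counts(rr, threshold_ms: float = PNN_THRESHOLD_MS) -> ThresholdCounts:
    """Directional pNN30: percent of deltas > +30 ms and < -30 ms."""
    dx = successive_differences(rr)
    n = len(dx)
    return ThresholdCounts(
        pnn30dec=float(100.0 * np.sum(dx > threshold_ms) / n),
        pnn30acc=float(100.0 * np.sum(dx < -threshold_ms) / n),
    )
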