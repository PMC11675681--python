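"""Windowing of recordings and rule-based stage / transition labeling.

Recordings are cut into consecutive half-open 5-minute windows; each window
gets per-stage occupancy fractions on a 0.1 grid (rounded half-up), a
"certain stage" indicator when one stage occupies at least 0.7 of the window,
and transition indicators for seven stage pairs following two rules:

rule A -- both the starting and ending stage are present, the ending stage's
fraction is at most 0.6 and has not decreased relative to the previous
window (the previous fraction of the first window is taken as 0);

rule B -- the starting stage is present, the ending stage is absent, but it
appears in the next window with a fraction of at most 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, CoverageError, EmptyInputError
from .rr_io import Hypnogram, RRSeries, STAGES

WINDOW_S = 300.0
CERTAIN_THRESHOLD = 0.7
TRANSITION_THRESHOLD = 0.6

#: the seven modeled transitions (start stage, end stage)
DEFAULT_TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("N1", "N2"),
    ("N2", "N3"),
    ("N2", "R"),
    ("N3", "N2"),
    ("N3", "R"),
    ("R", "N2"),
    ("W", "N1"),
)


def transition_name(start: str, end: str) -> str:
    return f"{start}-{end}"


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.35 -> 0.4 at one digit), unlike banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Segment:
    index: int
    start_s: float
    end_s: float
    rr: RRSeries


@dataclass
class StageFractions:
    segment_index: int
    fractions: dict[str, float]


def make_segments(rr: RRSeries, window_s: float = WINDOW_S) -> list[Segment]:
    """Cut a recording into consecutive non-overlapping windows.

    An interval belongs to the window containing its onset; a trailing
    partial window is dropped.
    """
    total = rr.duration_s
    n_windows = int(total // window_s)
    if n_windows == 0:
        raise EmptyInputError(
            f"recording of {total:.0f} s is shorter than one {window_s:.0f} s window"
        )
    onset_window = np.floor(rr.t_cum / window_s).astype(int)
    out = []
    for k in range(n_windows):
        m = onset_window == k
        sub = RRSeries(rr.subject_id, rr.intervals[m], rr.annotations[m])
        out.append(Segment(k, k * window_s, (k + 1) * window_s, sub))
    return out


def stage_overlap_seconds(
    start_s: float, end_s: float, hyp: Hypnogram
) -> dict[str, float]:
    """Exact (unrounded) seconds of overlap of [start_s, end_s) per stage."""
    if start_s < 0 or end_s > hyp.end_s + 1e-9:
        raise CoverageError(
            f"segment [{start_s}, {end_s}) outside hypnogram span [0, {hyp.end_s})"
        )
    overlap = dict.fromkeys(STAGES, 0.0)
    for stage, a, b in hyp.bouts:
        lo, hi = max(a, start_s), min(b, end_s)
        if hi > lo:
            overlap[stage] += hi - lo
    return overlap


def stage_fractions(
    segment: tuple[float, float], hyp: Hypnogram, segment_index: int = 0
) -> StageFractions:
    """Per-stage fraction of the window, each rounded half-up to one decimal."""
    start_s, end_s = segment
    overlap = stage_overlap_seconds(start_s, end_s, hyp)
    width = end_s - start_s
    fractions = {s: round_half_up(v / width, 1) for s, v in overlap.items()}
    return StageFractions(segment_index, fractions)


def certain_stage(
    fr: StageFractions | Mapping[str, float],
    threshold: float = CERTAIN_THRESHOLD,
) -> dict[str, int]:
    """Indicator per stage: 1 iff its fraction is >= threshold (0.7)."""
    fractions = fr.fractions if isinstance(fr, StageFractions) else fr
    return {s: int(fractions.get(s, 0.0) >= threshold) for s in STAGES}


def mark_transitions(
    frac_series: pd.DataFrame | Sequence[StageFractions],
    pairs: Sequence[tuple[str, str]] = DEFAULT_TRANSITIONS,
    threshold: float = TRANSITION_THRESHOLD,
) -> pd.DataFrame:
    """Per-segment transition indicators for one recording.

    ``frac_series`` is either a DataFrame with one column per stage (rows in
    segment order) or a sequence of :class:`StageFractions`.
    """
    if not isinstance(frac_series, pd.DataFrame):
        frac_series = pd.DataFrame(
            [fr.fractions for fr in frac_series],
            index=[fr.segment_index for fr in frac_series],
        )
    for start, end in pairs:
        if start not in STAGES or end not in STAGES or start == end:
            raise ConfigError(f"unknown transition pair {(start, end)!r}")
        if start not in frac_series.columns or end not in frac_series.columns:
            raise ConfigError(f"fraction columns missing for pair {(start, end)!r}")

    T = len(frac_series)
    out = pd.DataFrame(index=frac_series.index)
    for start, end in pairs:
        f_s = frac_series[start].to_numpy(dtype=float)
        f_e = frac_series[end].to_numpy(dtype=float)
        prev_e = np.concatenate(([0.0], f_e[:-1]))
        next_e = np.concatenate((f_e[1:], [np.nan]))
        rule_a = (f_s > 0) & (f_e > 0) & (f_e <= threshold) & (f_e >= prev_e)
        rule_b = (
            (f_s > 0)
            & (f_e == 0)
            & (np.arange(T) < T - 1)
            & (next_e > 0)
            & (next_e <= threshold)
        )
        out[transition_name(start, end)] = (rule_a | rule_b).astype(int)
    return out
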