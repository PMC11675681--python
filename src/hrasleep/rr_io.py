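"""I/O and validation for RR-interval series and hypnograms.

RR intervals are beat-to-beat times in milliseconds; the cumulative time axis
is in seconds. Two plain-text dialects are supported: a bare one-interval-per-
line file and a two-column CSV ``interval_ms,annotation`` with header.
Hypnograms are CSVs ``stage,start_s,end_s`` over the vocabulary
W / N1 / N2 / N3 / R, with contiguous non-overlapping bouts starting at 0 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConfigError,
    EmptyInputError,
    FormatError,
    LabelError,
    StructureError,
)

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

NORMAL = "normal"
ARTIFACT = "artifact"

#: hard validity bounds — anything outside raises
HARD_MIN_MS, HARD_MAX_MS = 0.0, 5000.0
#: physiologic plausibility window — outside is auto-flagged artifact
PHYSIO_MIN_MS, PHYSIO_MAX_MS = 200.0, 3000.0


@dataclass
class RRSeries:
    """One subject's RR-interval series with per-beat annotations.

    Attributes
    ----------
    subject_id : str
    intervals : ndarray of float, ms, all in (0, 5000)
    annotations : ndarray of str, each ``"normal"`` or ``"artifact"``
    """

    subject_id: str
    intervals: np.ndarray
    annotations: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise FormatError("intervals must be one-dimensional")
        if self.annotations is None:
            self.annotations = _auto_annotations(self.intervals)
        self.annotations = np.asarray(self.annotations, dtype=object)
        if len(self.annotations) != len(self.intervals):
            raise FormatError(
                "annotations and intervals differ in length: "
                f"{len(self.annotations)} vs {len(self.intervals)}"
            )
        bad = set(self.annotations) - {NORMAL, ARTIFACT}
        if bad:
            raise FormatError(f"unknown annotations: {sorted(map(str, bad))}")
        if len(self.intervals) and (
            self.intervals.min() <= HARD_MIN_MS or self.intervals.max() >= HARD_MAX_MS
        ):
            raise FormatError(
                f"intervals must lie in ({HARD_MIN_MS:g}, {HARD_MAX_MS:g}) ms"
            )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def t_cum(self) -> np.ndarray:
        """Onset time of each interval in seconds; ``t_cum[0] == 0``."""
        if len(self.intervals) == 0:
            return np.empty(0)
        return np.concatenate(([0.0], np.cumsum(self.intervals[:-1]) / 1000.0))

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum() / 1000.0)

    @property
    def is_normal(self) -> np.ndarray:
        return self.annotations == NORMAL

    def replace(self, intervals: np.ndarray, annotations: np.ndarray) -> "RRSeries":
        return RRSeries(self.subject_id, intervals, annotations)


def _auto_annotations(intervals: np.ndarray) -> np.ndarray:
    ann = np.full(len(intervals), NORMAL, dtype=object)
    out = (intervals <= PHYSIO_MIN_MS) | (intervals >= PHYSIO_MAX_MS)
    ann[out] = ARTIFACT
    return ann


@dataclass
class Hypnogram:
    """Expert-scored sleep stages as contiguous bouts ``(stage, start_s, end_s)``."""

    subject_id: str
    bouts: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if not self.bouts:
            raise EmptyInputError("hypnogram has no bouts")
        self.bouts = [(str(s), float(a), float(b)) for s, a, b in self.bouts]
        for stage, start, end in self.bouts:
            if stage not in STAGES:
                raise LabelError(f"unknown stage label {stage!r}")
            if not end > start:
                raise StructureError(f"bout ({stage},{start},{end}) has end <= start")
        if self.bouts[0][1] != 0.0:
            raise StructureError("first bout must start at 0 s")
        for (s0, a0, b0), (s1, a1, b1) in zip(self.bouts, self.bouts[1:]):
            if b0 != a1:
                kind = "gap" if b0 < a1 else "overlap"
                raise StructureError(
                    f"{kind} between bouts ending {b0} s and starting {a1} s"
                )

    @property
    def end_s(self) -> float:
        return self.bouts[-1][2]

    def stage_at(self, t: float) -> str:
        """Stage containing time ``t`` (half-open bouts; the end time belongs
        to the following bout, the final end time to the final bout)."""
        starts = [a for _, a, _ in self.bouts]
        k = int(np.searchsorted(starts, t, side="right")) - 1
        k = min(max(k, 0), len(self.bouts) - 1)
        return self.bouts[k][0]


# ---------------------------------------------------------------------------
# file I/O

_RR_HEADER = "interval_ms,annotation"
_HYP_HEADER = "stage,start_s,end_s"


def read_rr(path: str | Path, dialect: str = "auto", subject_id: str | None = None) -> RRSeries:
    """Read an RR series from a one-column or two-column text file.

    Rows flagged ``artifact`` in the file are kept but marked; intervals
    outside the (200, 3000) ms plausibility window are auto-flagged artifact.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise EmptyInputError(f"{path}: empty RR file")
    if dialect == "auto":
        dialect = "two-column" if lines[0].lower() == _RR_HEADER else "one-column"
    if dialect not in ("one-column", "two-column"):
        raise FormatError(f"unknown RR dialect {dialect!r}")

    intervals: list[float] = []
    annotations: list[str] = []
    start = 0
    if dialect == "two-column" and lines[0].lower() == _RR_HEADER:
        start = 1
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        parts = raw.split(",") if dialect == "two-column" else [raw]
        try:
            value = float(parts[0])
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: cannot parse {raw!r}") from exc
        ann = None
        if dialect == "two-column" and len(parts) > 1 and parts[1]:
            ann = parts[1].strip().lower()
            if ann not in (NORMAL, ARTIFACT):
                raise FormatError(f"{path}, line {lineno}: bad annotation {parts[1]!r}")
        if ann is None:
            ann = NORMAL
        if value <= PHYSIO_MIN_MS or value >= PHYSIO_MAX_MS:
            ann = ARTIFACT
        intervals.append(value)
        annotations.append(ann)
    if not intervals:
        raise EmptyInputError(f"{path}: no data rows")
    sid = subject_id if subject_id is not None else path.stem
    return RRSeries(sid, np.array(intervals), np.array(annotations, dtype=object))


def write_rr(rr: RRSeries, path: str | Path, dialect: str = "two-column") -> None:
    path = Path(path)
    if dialect == "one-column":
        body = "\n".join(f"{v:g}" for v in rr.intervals)
    elif dialect == "two-column":
        rows = (f"{v:g},{a}" for v, a in zip(rr.intervals, rr.annotations))
        body = _RR_HEADER + "\n" + "\n".join(rows)
    else:
        raise FormatError(f"unknown RR dialect {dialect!r}")
    path.write_text(body + "\n")


def read_hypnogram(path: str | Path, subject_id: str | None = None) -> Hypnogram:
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: empty hypnogram file")
    if lines[0].lower() == _HYP_HEADER:
        lines = lines[1:]
    bouts: list[tuple[str, float, float]] = []
    for lineno, raw in enumerate(lines, start=1):
        parts = [p.strip() for p in raw.split(",")]
        if len(parts) != 3:
            raise FormatError(f"{path}, line {lineno}: expected 'stage,start_s,end_s'")
        stage = parts[0]
        try:
            start, end = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: cannot parse {raw!r}") from exc
        bouts.append((stage, start, end))
    sid = subject_id if subject_id is not None else path.stem
    return Hypnogram(sid, bouts)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    rows = (f"{s},{a:g},{b:g}" for s, a, b in hyp.bouts)
    Path(path).write_text(_HYP_HEADER + "\n" + "\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# artifact handling


def mask_artifacts(rr: RRSeries, policy: str = "split"):
    """Remove or isolate artifact beats.

    ``policy="drop"`` removes artifact beats and concatenates their neighbours
    (one shorter series); ``policy="split"`` breaks the series at every
    artifact so that no successive-difference pair ever spans an edited beat
    (a list of sub-series).
    """
    normal = rr.is_normal
    if not normal.any():
        raise EmptyInputError(f"{rr.subject_id}: series is all-artifact")
    if policy == "drop":
        return rr.replace(rr.intervals[normal], rr.annotations[normal])
    if policy == "split":
        pieces: list[RRSeries] = []
        idx = np.flatnonzero(~normal)
        bounds = np.concatenate(([-1], idx, [len(rr)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a > 1:
                sl = slice(a + 1, b)
                pieces.append(rr.replace(rr.intervals[sl], rr.annotations[sl]))
        return pieces
    raise ConfigError(f"unknown artifact policy {policy!r}")
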