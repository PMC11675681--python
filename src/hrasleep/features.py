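"""Per-segment feature extraction and segment-table assembly.

Turns one (RR series, hypnogram) pair into the analysis table: one row per
5-min segment carrying the HRV / asymmetry / complexity descriptors, stage
fractions, certain-stage indicators and transition indicators, keyed by
subject.  Segments without enough usable beats get missing feature values;
the modeling layer drops and counts such rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hra_features, hrv_spectral, hrv_time
from .complexity import sampen
from .errors import InsufficientDataError
from .rr_io import Hypnogram, RRSeries, STAGES, mask_artifacts
from .segmentation import (
    DEFAULT_TRANSITIONS,
    WINDOW_S,
    certain_stage,
    make_segments,
    mark_transitions,
    stage_fractions,
)

FEATURE_COLUMNS = (
    "SDNN",
    "SD1",
    "SD2",
    "SampEn",
    "LF_HF",
    "pnn30",
    "SD1a",
    "SD1d",
    "pnn30dec",
    "pnn30acc",
    "AR4",
    "DR4",
    "ARMAX",
    "DRMAX",
    "HDR",
    "HAR",
)


@dataclass
class FeatureParams:
    sampen_m: int = 2
    sampen_r: float = 0.2
    sampen_r_units: str = "sd"
    spectral_method: str = "welch"
    resample_hz: float = 4.0
    welch_window_s: float = 120.0
    entropy_base: float = 2.0
    artifact_policy: str = "split"
    window_s: float = WINDOW_S


def segment_features(rr: RRSeries, params: FeatureParams | None = None) -> dict:
    """Feature row for one segment's RR sub-series.

    Artifact beats are handled per ``params.artifact_policy``; with the
    default ``split`` policy no successive-difference pair, Poincaré pair or
    run ever bridges an edited beat.
    """
    params = params or FeatureParams()
    row: dict[str, float] = {c: np.nan for c in FEATURE_COLUMNS}
    row["n_beats"] = len(rr)
    row["n_artifacts"] = int((~rr.is_normal).sum())
    try:
        masked = mask_artifacts(rr, params.artifact_policy)
    except Exception:
        return row
    pieces = (
        [m.intervals for m in masked]
        if isinstance(masked, list)
        else [masked.intervals]
    )

    try:
        row["SDNN"] = hrv_time.sdnn(pieces)
        row["pnn30"] = hrv_time.pnn30(pieces)
    except InsufficientDataError:
        pass
    try:
        row["SD1"] = hrv_time.sd1(pieces)
        row["SD2"] = hrv_time.sd2(pieces)
        vd = hra_features.variance_decomposition(pieces)
        row["SD1d"], row["SD1a"] = vd.sd1d, vd.sd1a
    except InsufficientDataError:
        pass
    try:
        tc = hra_features.threshold_counts(pieces)
        row["pnn30dec"], row["pnn30acc"] = tc.pnn30dec, tc.pnn30acc
        dist = hra_features.runs_partition(pieces)
        row["DR4"] = dist.dr_counts.get(4, 0)
        row["AR4"] = dist.ar_counts.get(4, 0)
        row["DRMAX"], row["ARMAX"] = dist.dr_max, dist.ar_max
        ent = hra_features.runs_entropy(dist, base=params.entropy_base)
        row["HDR"], row["HAR"] = ent.hdr, ent.har
    except InsufficientDataError:
        pass

    # complexity on the longest unbroken piece so templates never span edits
    longest = max(pieces, key=len)
    try:
        row["SampEn"] = sampen(
            longest, m=params.sampen_m, r=params.sampen_r, r_units=params.sampen_r_units
        )
    except InsufficientDataError:
        pass

    # spectral features use the onset times of the normal beats
    normal = rr.is_normal
    try:
        bp = hrv_spectral.band_powers(
            rr.intervals[normal],
            rr.t_cum[normal],
            method=params.spectral_method,
            resample_hz=params.resample_hz,
            welch_window_s=params.welch_window_s,
        )
        row["LF_power"], row["HF_power"] = bp.lf_power, bp.hf_power
        row["LF_HF"] = bp.lf_hf
    except InsufficientDataError:
        pass
    return row


def build_segment_table(
    rr: RRSeries,
    hyp: Hypnogram,
    params: FeatureParams | None = None,
    transitions=DEFAULT_TRANSITIONS,
) -> pd.DataFrame:
    """Full per-segment table for one recording."""
    params = params or FeatureParams()
    segments = make_segments(rr, params.window_s)
    # only segments covered by the hypnogram can be labeled
    segments = [s for s in segments if s.end_s <= hyp.end_s + 1e-9]
    rows = []
    frac_rows = []
    for seg in segments:
        fr = stage_fractions((seg.start_s, seg.end_s), hyp, seg.index)
        frac_rows.append(fr)
        row = {"subject_id": rr.subject_id, "segment_index": seg.index}
        row.update(segment_features(seg.rr, params))
        for stage in STAGES:
            row[f"frac_{stage}"] = fr.fractions[stage]
        for stage, flag in certain_stage(fr).items():
            row[f"certain_{stage}"] = flag
        rows.append(row)
    table = pd.DataFrame(rows)
    frac_df = pd.DataFrame([fr.fractions for fr in frac_rows])
    trans = mark_transitions(frac_df, transitions)
    return pd.concat([table, trans.reset_index(drop=True)], axis=1)


def cohort_segment_table(
    cohort,
    params: FeatureParams | None = None,
    transitions=DEFAULT_TRANSITIONS,
) -> pd.DataFrame:
    """Concatenated segment tables of a list of (RRSeries, Hypnogram) pairs."""
    tables = [build_segment_table(rr, hyp, params, transitions) for rr, hyp in cohort]
    return pd.concat(tables, ignore_index=True)
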