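"""End-to-end orchestration: features -> labels -> split -> models -> metrics.

``run_pipeline`` runs the whole analysis on either a directory of RR /
hypnogram files or a synthetic cohort, fits one one-vs-all GEE per response
(5 certain stages + 7 transitions by default), evaluates the selected models
on held-out subjects, and writes the segment table, model reports,
evaluation report and a manifest to the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DegenerateResponseError, FitError, UndefinedMetricError
from .evaluation import auc as auc_score
from .evaluation import confusion, metrics, stage_distribution
from .features import FeatureParams, cohort_segment_table
from .gee_modeling import (
    ALL_COVARIATES,
    ModelSpec,
    backward_select,
    predict_proba,
    stratified_subject_split,
)
from .rr_io import STAGES, read_hypnogram, read_rr
from .segmentation import DEFAULT_TRANSITIONS, transition_name
from .synthetic_data import CohortConfig, DEFAULT_DYNAMICS, generate_cohort

log = logging.getLogger("hrasleep")

DEFAULT_RESPONSES = tuple(f"certain_{s}" for s in STAGES) + tuple(
    transition_name(a, b) for a, b in DEFAULT_TRANSITIONS
)


@dataclass
class RunConfig:
    input_dir: str | None = None  # directory of *_rr.csv / *_hyp.csv files
    synthetic: CohortConfig | None = None  # used when input_dir is None
    features: FeatureParams = field(default_factory=FeatureParams)
    responses: tuple[str, ...] = DEFAULT_RESPONSES
    covariates: tuple[str, ...] = ALL_COVARIATES
    corr_structure: str = "exchangeable"
    criterion: str = "aic_independence"
    train_frac: float = 0.7
    n_strata: int = 4
    seed: int = 0
    threshold: float = 0.5
    fallback_to_train: bool = True  # evaluate on train when test is single-class
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "features" in raw:
            raw["features"] = FeatureParams(**raw["features"])
        if "synthetic" in raw:
            raw["synthetic"] = CohortConfig(**raw["synthetic"])
        for key in ("responses", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def load_cohort(input_dir: str | Path):
    input_dir = Path(input_dir)
    pairs = []
    for rr_path in sorted(input_dir.glob("*_rr.csv")):
        sid = rr_path.name[: -len("_rr.csv")]
        hyp_path = input_dir / f"{sid}_hyp.csv"
        rr = read_rr(rr_path, subject_id=sid)
        hyp = read_hypnogram(hyp_path, subject_id=sid)
        pairs.append((rr, hyp))
    if not pairs:
        raise FileNotFoundError(f"no *_rr.csv recordings under {input_dir}")
    return pairs


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a dict of in-memory artifacts."""
    if cfg.input_dir is not None:
        cohort = load_cohort(cfg.input_dir)
        log.info("loaded %d recordings from %s", len(cohort), cfg.input_dir)
    else:
        syn = cfg.synthetic or CohortConfig()
        cohort = generate_cohort(syn, DEFAULT_DYNAMICS, seed=cfg.seed)
        log.info("generated %d synthetic recordings", len(cohort))

    table = cohort_segment_table(cohort, cfg.features)
    log.info("segment table: %d rows x %d columns", *table.shape)

    distribution = stage_distribution(table)
    plan = stratified_subject_split(
        table, cfg.train_frac, cfg.n_strata, seed=cfg.seed
    )
    train = table[table.subject_id.isin(plan.train_subjects)]
    test = table[table.subject_id.isin(plan.test_subjects)]

    model_reports: dict[str, dict] = {}
    eval_rows = []
    for response in cfg.responses:
        report: dict = {"response": response}
        try:
            spec = ModelSpec(
                response=response,
                covariates=cfg.covariates,
                corr_structure=cfg.corr_structure,
            )
            fit = backward_select(train, spec, cfg.criterion)
            report.update(
                status="ok",
                coefficients=fit.summary_frame().to_dict(),
                alpha=fit.alpha,
                n_clusters=fit.n_clusters,
                n_obs=fit.n_obs,
                n_dropped_rows=fit.n_dropped_rows,
                criterion=fit.criterion,
                criterion_value=fit.criterion_value,
                selection_trace=fit.selection_trace,
            )
        except (DegenerateResponseError, FitError) as exc:
            report.update(status="failed", reason=str(exc))
            model_reports[response] = report
            log.warning("model %s failed: %s", response, exc)
            continue

        eval_set, eval_name = test, "test"
        needed = [response, *fit.covariates]
        rows = eval_set.dropna(subset=needed)
        if rows[response].nunique() < 2 and cfg.fallback_to_train:
            eval_set, eval_name = train, "train"
            rows = eval_set.dropna(subset=needed)
        try:
            probs = predict_proba(fit, rows)
            labels = rows[response].astype(int).to_numpy()
            cm = confusion(labels, probs, cfg.threshold)
            rep = metrics(cm)
            rep.auc = auc_score(labels, probs)
            eval_rows.append(
                {
                    "response": response,
                    "evaluated_on": eval_name,
                    "n": cm.total,
                    "tn": cm.tn,
                    "fp": cm.fp,
                    "fn": cm.fn,
                    "tp": cm.tp,
                    **{k: getattr(rep.rounded(), k) for k in
                       ("auc", "accuracy", "precision", "recall", "f1")},
                }
            )
        except (UndefinedMetricError, ValueError) as exc:
            eval_rows.append({"response": response, "evaluated_on": eval_name,
                              "error": str(exc)})
        model_reports[response] = report
        log.info("model %s: ok (%d covariates kept)", response, len(fit.covariates))

    evaluation = pd.DataFrame(eval_rows)
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_cfg_dict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "n_subjects": int(table.subject_id.nunique()),
        "n_segments": int(len(table)),
        "train_subjects": list(plan.train_subjects),
        "test_subjects": list(plan.test_subjects),
        "achieved_train_fraction": plan.achieved_train_fraction,
        "responses_ok": [r for r, rep in model_reports.items() if rep["status"] == "ok"],
    }

    artifacts = {
        "segment_table": table,
        "distribution": distribution,
        "split": plan,
        "model_reports": model_reports,
        "evaluation": evaluation,
        "manifest": manifest,
    }
    if cfg.out_dir:
        _write_artifacts(artifacts, Path(cfg.out_dir))
    return artifacts


def _cfg_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d


def _write_artifacts(artifacts: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    artifacts["segment_table"].to_csv(out / "segment_table.csv", index=False)
    artifacts["distribution"].to_csv(out / "stage_distribution.csv")
    artifacts["evaluation"].to_csv(out / "evaluation.csv", index=False)
    (out / "model_reports.json").write_text(
        json.dumps(artifacts["model_reports"], indent=2, default=float)
    )
    (out / "manifest.json").write_text(
        json.dumps(artifacts["manifest"], indent=2, default=str)
    )
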