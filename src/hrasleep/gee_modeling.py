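"""One-vs-all GEE logistic models with subject clustering.

Each binary response (a certain stage or a transition) is modeled marginally
with a binomial GEE: subjects are the clusters, the working correlation
R(alpha) is exchangeable by default (independence and AR(1) available), and
inference uses the robust sandwich covariance.  Backward selection drops one
covariate at a time, accepting the drop that most lowers the criterion; the
default criterion is the AIC of the corresponding independence (ordinary
logistic) fit, with QIC as the alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans
from statsmodels.genmod.cov_struct import Autoregressive, Exchangeable, Independence

from .errors import (
    ConfigError,
    DegenerateResponseError,
    FitError,
    SchemaError,
    SplitError,
)

#: the modeled covariate vocabulary
SYMMETRIC_COVARIATES = ("SDNN", "SD1", "SampEn", "LF_HF", "pnn30")
ASYMMETRIC_COVARIATES = (
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
ALL_COVARIATES = SYMMETRIC_COVARIATES + ASYMMETRIC_COVARIATES


@dataclass
class ModelSpec:
    response: str
    covariates: tuple[str, ...] = ALL_COVARIATES
    cluster: str = "subject_id"
    corr_structure: str = "exchangeable"

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        if not self.covariates:
            raise ConfigError("covariates must be non-empty")
        if len(set(self.covariates)) != len(self.covariates):
            raise ConfigError("duplicate covariates")
        if self.corr_structure not in ("independence", "exchangeable", "ar1"):
            raise ConfigError(f"unknown correlation structure {self.corr_structure!r}")


@dataclass
class GEEFit:
    spec: ModelSpec
    coef: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    alpha: float
    n_clusters: int
    n_obs: int
    n_dropped_rows: int
    criterion: str | None = None
    criterion_value: float = float("nan")
    selection_trace: list[tuple[str, float]] = field(default_factory=list)
    dropped_constant: tuple[str, ...] = ()

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(k for k in self.coef if k != "Intercept")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "z": self.z, "p": self.p}
        )


def _cov_struct(name: str):
    return {
        "independence": Independence,
        "exchangeable": Exchangeable,
        "ar1": Autoregressive,
    }[name]()


def _design(table: pd.DataFrame, spec: ModelSpec):
    missing = [c for c in (spec.response, spec.cluster, *spec.covariates) if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    cols = [spec.response, spec.cluster, *spec.covariates]
    sub = table[cols].replace([np.inf, -np.inf], np.nan)
    kept = sub.dropna()
    n_dropped = len(sub) - len(kept)
    y = kept[spec.response].astype(float)
    if y.nunique() < 2:
        raise DegenerateResponseError(
            f"response {spec.response!r} has a single class after row filtering"
        )
    # constant covariates carry no information and break the fit
    constant = tuple(c for c in spec.covariates if kept[c].nunique() <= 1)
    usable = [c for c in spec.covariates if c not in constant]
    X = sm.add_constant(kept[usable].astype(float))
    X = X.rename(columns={"const": "Intercept"})
    return y, X, kept[spec.cluster], n_dropped, constant


def fit_gee(table: pd.DataFrame, spec: ModelSpec) -> GEEFit:
    """Fit one binomial GEE with robust (sandwich) standard errors."""
    y, X, groups, n_dropped, constant = _design(table, spec)
    cov = _cov_struct(spec.corr_structure)
    kwargs = {}
    if spec.corr_structure == "ar1":
        kwargs["time"] = (
            table.loc[X.index, "segment_index"].to_numpy()[:, None]
            if "segment_index" in table.columns
            else np.arange(len(X))[:, None]
        )
    model = sm.GEE(
        y, X, groups=groups, family=sm.families.Binomial(), cov_struct=cov, **kwargs
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(maxiter=200)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise FitError(f"GEE fit failed for {spec.response!r}: {exc}") from exc
    if not np.all(np.isfinite(result.params)):
        raise FitError(f"GEE fit diverged for {spec.response!r} (separation?)")
    alpha = cov.dep_params  # None for independence
    alpha = float(np.atleast_1d(alpha)[0]) if alpha is not None and np.size(alpha) else 0.0
    return GEEFit(
        spec=spec,
        coef=dict(result.params),
        se=dict(result.bse),
        z=dict(result.tvalues),
        p=dict(result.pvalues),
        alpha=alpha,
        n_clusters=groups.nunique(),
        n_obs=len(X),
        n_dropped_rows=n_dropped,
        dropped_constant=constant,
    )


def _criterion_value(table, spec: ModelSpec, criterion: str) -> float:
    if criterion == "aic_independence":
        y, X, _, _, _ = _design(table, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(sm.GLM(y, X, family=sm.families.Binomial()).fit().aic)
    if criterion == "qic":
        y, X, groups, _, _ = _design(table, spec)
        cov = _cov_struct(spec.corr_structure)
        model = sm.GEE(y, X, groups=groups, family=sm.families.Binomial(), cov_struct=cov)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200)
            return float(res.qic(res.scale)[0])
    raise ConfigError(f"unknown selection criterion {criterion!r}")


def backward_select(
    table: pd.DataFrame,
    full_spec: ModelSpec,
    criterion: str = "aic_independence",
) -> GEEFit:
    """Backward covariate elimination.

    At each step the single covariate whose removal yields the lowest
    criterion is dropped, as long as that improves on the current model; the
    intercept is never dropped.  Returns the final GEE fit with the ordered
    trace of accepted drops.
    """
    current = list(full_spec.covariates)
    current_value = _criterion_value(table, full_spec, criterion)
    trace: list[tuple[str, float]] = []
    while len(current) > 1:
        candidates = []
        for drop in current:
            reduced = ModelSpec(
                response=full_spec.response,
                covariates=tuple(c for c in current if c != drop),
                cluster=full_spec.cluster,
                corr_structure=full_spec.corr_structure,
            )
            try:
                candidates.append((_criterion_value(table, reduced, criterion), drop))
            except (FitError, DegenerateResponseError):
                continue
        if not candidates:
            break
        best_value, best_drop = min(candidates)
        if best_value >= current_value:
            break
        current.remove(best_drop)
        current_value = best_value
        trace.append((best_drop, best_value))
    final_spec = ModelSpec(
        response=full_spec.response,
        covariates=tuple(current),
        cluster=full_spec.cluster,
        corr_structure=full_spec.corr_structure,
    )
    fit = fit_gee(table, final_spec)
    fit.criterion = criterion
    fit.criterion_value = current_value
    fit.selection_trace = trace
    return fit


def predict_proba(fit: GEEFit, rows: pd.DataFrame) -> np.ndarray:
    """Logistic probabilities from a fitted model's coefficients."""
    missing = [c for c in fit.covariates if c not in rows.columns]
    if missing:
        raise SchemaError(f"rows are missing covariates: {missing}")
    lin = np.full(len(rows), fit.coef.get("Intercept", 0.0))
    for c in fit.covariates:
        lin = lin + fit.coef[c] * rows[c].to_numpy(dtype=float)
    return 1.0 / (1.0 + np.exp(-lin))


# ---------------------------------------------------------------------------
# subject-level stratified split


@dataclass
class SplitPlan:
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    strata: dict[str, int]
    achieved_train_fraction: float


def stratified_subject_split(
    table: pd.DataFrame,
    train_frac: float = 0.7,
    n_strata: int = 4,
    seed: int = 0,
    cluster: str = "subject_id",
) -> SplitPlan:
    """Whole-subject train/test split stratified on stage composition.

    Subjects are grouped by k-means on their per-subject stage-share vectors
    and roughly ``train_frac`` of the subjects of every stratum are assigned
    to the training set; all segments of a subject stay together.
    """
    subjects = table[cluster].unique()
    if len(subjects) < 3:
        raise SplitError("need at least 3 subjects to split")
    share_cols = [c for c in table.columns if c.startswith("frac_")]
    if not share_cols:
        share_cols = [c for c in table.columns if c.startswith("certain_")]
    if not share_cols:
        raise SchemaError("no stage-share columns to stratify on")
    comp = table.groupby(cluster)[share_cols].mean()
    k = int(min(n_strata, max(1, len(subjects) // 2)))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    strata = dict(zip(comp.index, km.fit_predict(comp.to_numpy())))

    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for stratum in sorted(set(strata.values())):
        members = sorted(s for s, g in strata.items() if g == stratum)
        rng.shuffle(members)
        n_train = int(round(train_frac * len(members)))
        if len(members) >= 2:
            n_train = min(max(n_train, 1), len(members) - 1)
        train.extend(members[:n_train])
        test.extend(members[n_train:])
    seg_counts = table[cluster].value_counts()
    achieved = float(seg_counts[train].sum() / seg_counts.sum())
    return SplitPlan(
        train_subjects=tuple(sorted(train)),
        test_subjects=tuple(sorted(test)),
        strata={str(s): int(g) for s, g in strata.items()},
        achieved_train_fraction=achieved,
    )
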