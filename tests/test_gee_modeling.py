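import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hrasleep.errors import ConfigError, DegenerateResponseError, SchemaError, SplitError
from hrasleep.gee_modeling import (
    GEEFit,
    ModelSpec,
    backward_select,
    fit_gee,
    predict_proba,
    stratified_subject_split,
)


def simulate_clustered(
    rng,
    n_clusters=30,
    cluster_size=40,
    beta=(1.0,),
    intercept=-1.0,
    cluster_sd=0.7,
    n_noise=0,
):
    """Clustered logistic data with known coefficients and a shared
    per-cluster random intercept (induces exchangeable correlation)."""
    rows = []
    for c in range(n_clusters):
        u = rng.normal(0, cluster_sd)
        x = rng.normal(0, 1, size=(cluster_size, len(beta) + n_noise))
        lin = intercept + u + x[:, : len(beta)] @ np.array(beta)
        y = rng.random(cluster_size) < 1 / (1 + np.exp(-lin))
        for i in range(cluster_size):
            row = {"subject_id": f"c{c:02d}", "y": int(y[i]), "segment_index": i}
            for j in range(x.shape[1]):
                row[f"x{j}"] = x[i, j]
            rows.append(row)
    return pd.DataFrame(rows)


class TestFitGEE:
    def test_singleton_clusters_equal_ordinary_logistic(self, rng):
        n = 300
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "x0": rng.normal(size=n),
            }
        )
        df["y"] = (rng.random(n) < 1 / (1 + np.exp(-(0.8 * df.x0 - 0.5)))).astype(int)
        fit = fit_gee(df, ModelSpec("y", ("x0",), corr_structure="independence"))
        mle = sm.Logit(df.y, sm.add_constant(df.x0)).fit(disp=0)
        assert fit.coef["Intercept"] == pytest.approx(mle.params["const"], abs=1e-6)
        assert fit.coef["x0"] == pytest.approx(mle.params["x0"], abs=1e-6)

    def test_constant_covariate_is_excluded(self, rng):
        df = simulate_clustered(rng, n_clusters=10, cluster_size=20)
        df["flat"] = 0.0
        fit = fit_gee(df, ModelSpec("y", ("x0", "flat")))
        assert "flat" not in fit.coef
        assert fit.dropped_constant == ("flat",)

    def test_parameter_recovery_with_cluster_effects(self, rng):
        df = simulate_clustered(rng, n_clusters=30, cluster_size=100, beta=(1.0,))
        fit = fit_gee(df, ModelSpec("y", ("x0",)))
        assert fit.coef["x0"] == pytest.approx(1.0, abs=0.2)
        assert fit.alpha > 0

    def test_single_class_response_raises(self, rng):
        df = simulate_clustered(rng, n_clusters=5, cluster_size=10)
        df["y"] = 1
        with pytest.raises(DegenerateResponseError):
            fit_gee(df, ModelSpec("y", ("x0",)))

    def test_exchangeable_alpha_shrinks_after_shuffling(self, rng):
        df = simulate_clustered(rng, n_clusters=25, cluster_size=60, cluster_sd=1.0)
        fit = fit_gee(df, ModelSpec("y", ("x0",)))
        shuffled = df.copy()
        shuffled["subject_id"] = rng.permutation(shuffled.subject_id.to_numpy())
        fit_shuffled = fit_gee(shuffled, ModelSpec("y", ("x0",)))
        assert fit.alpha >= fit_shuffled.alpha

    def test_rescaling_covariate_rescales_coefficient(self, rng):
        df = simulate_clustered(rng, n_clusters=15, cluster_size=40)
        fit = fit_gee(df, ModelSpec("y", ("x0",)))
        df2 = df.copy()
        df2["x0"] = df2["x0"] * 10.0
        fit2 = fit_gee(df2, ModelSpec("y", ("x0",)))
        assert fit2.coef["x0"] == pytest.approx(fit.coef["x0"] / 10.0, rel=1e-5)

    def test_spec_validation(self):
        with pytest.raises(ConfigError):
            ModelSpec("y", ())
        with pytest.raises(ConfigError):
            ModelSpec("y", ("a", "a"))
        with pytest.raises(ConfigError):
            ModelSpec("y", ("a",), corr_structure="toeplitz")


class TestBackwardSelect:
    def test_strong_covariate_always_retained(self, rng):
        df = simulate_clustered(
            rng, n_clusters=25, cluster_size=80, beta=(1.2,), n_noise=4
        )
        covs = tuple(c for c in df.columns if c.startswith("x"))
        fit = backward_select(df, ModelSpec("y", covs))
        assert "x0" in fit.coef

    def test_null_model_sheds_noise_covariates(self, rng):
        kept = []
        for _ in range(5):
            df = simulate_clustered(
                rng, n_clusters=20, cluster_size=60, beta=(0.0,), n_noise=4
            )
            covs = tuple(c for c in df.columns if c.startswith("x"))
            fit = backward_select(df, ModelSpec("y", covs))
            kept.append(len(fit.covariates))
        assert sum(k <= 1 for k in kept) >= 4

    def test_trace_criterion_is_non_increasing(self, rng):
        df = simulate_clustered(rng, n_clusters=15, cluster_size=40, n_noise=5)
        covs = tuple(c for c in df.columns if c.startswith("x"))
        fit = backward_select(df, ModelSpec("y", covs))
        values = [v for _, v in fit.selection_trace]
        assert values == sorted(values, reverse=True)

    def test_qic_criterion_runs(self, rng):
        df = simulate_clustered(rng, n_clusters=10, cluster_size=30, n_noise=2)
        covs = tuple(c for c in df.columns if c.startswith("x"))
        fit = backward_select(df, ModelSpec("y", covs), criterion="qic")
        assert fit.criterion == "qic" and np.isfinite(fit.criterion_value)


class TestPredictProba:
    def test_null_model_gives_half(self):
        fit = GEEFit(
            spec=ModelSpec("y", ("x0",)),
            coef={"Intercept": 0.0, "x0": 0.0},
            se={}, z={}, p={}, alpha=0.0, n_clusters=2, n_obs=4, n_dropped_rows=0,
        )
        rows = pd.DataFrame({"x0": [-5.0, 0.0, 5.0]})
        np.testing.assert_allclose(predict_proba(fit, rows), 0.5)

    def test_matches_hand_computed_logistic(self, rng):
        coef = {"Intercept": -0.7, "a": 0.3, "b": -1.1}
        fit = GEEFit(
            spec=ModelSpec("y", ("a", "b")),
            coef=coef, se={}, z={}, p={}, alpha=0.0,
            n_clusters=2, n_obs=3, n_dropped_rows=0,
        )
        rows = pd.DataFrame({"a": rng.normal(size=3), "b": rng.normal(size=3)})
        expected = 1 / (1 + np.exp(-(-0.7 + 0.3 * rows.a - 1.1 * rows.b)))
        np.testing.assert_allclose(predict_proba(fit, rows), expected)

    def test_probability_decreases_with_intercept(self):
        rows = pd.DataFrame({"x0": [1.0]})
        probs = []
        for intercept in (2.0, 0.0, -2.0, -8.0):
            fit = GEEFit(
                spec=ModelSpec("y", ("x0",)),
                coef={"Intercept": intercept, "x0": 0.5},
                se={}, z={}, p={}, alpha=0.0, n_clusters=2, n_obs=1, n_dropped_rows=0,
            )
            probs.append(predict_proba(fit, rows)[0])
        assert probs == sorted(probs, reverse=True)
        assert probs[-1] < 0.01

    def test_missing_covariate_is_schema_error(self):
        fit = GEEFit(
            spec=ModelSpec("y", ("x0",)),
            coef={"Intercept": 0.0, "x0": 1.0},
            se={}, z={}, p={}, alpha=0.0, n_clusters=2, n_obs=1, n_dropped_rows=0,
        )
        with pytest.raises(SchemaError):
            predict_proba(fit, pd.DataFrame({"other": [1.0]}))


class TestStratifiedSplit:
    @staticmethod
    def _table(n_subjects, rng, n_segments=20):
        rows = []
        for i in range(n_subjects):
            for k in range(n_segments):
                rows.append(
                    {
                        "subject_id": f"s{i:02d}",
                        "frac_W": 0.5,
                        "frac_N2": 0.5,
                        "segment_index": k,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_subjects_split_seven_three(self, rng):
        plan = stratified_subject_split(self._table(10, rng), n_strata=1, seed=5)
        assert len(plan.train_subjects) == 7 and len(plan.test_subjects) == 3

    def test_deterministic_for_fixed_seed(self, rng):
        t = self._table(12, rng)
        a = stratified_subject_split(t, seed=9)
        b = stratified_subject_split(t, seed=9)
        assert a == b

    def test_disjoint_and_exhaustive(self, small_table):
        plan = stratified_subject_split(small_table, n_strata=2, seed=1)
        train, test = set(plan.train_subjects), set(plan.test_subjects)
        assert not train & test
        assert train | test == set(small_table.subject_id.unique())
        assert 0 < plan.achieved_train_fraction < 1

    def test_too_few_subjects(self, rng):
        with pytest.raises(SplitError):
            stratified_subject_split(self._table(2, rng))
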