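"""Selection, model fits, split bookkeeping and leakage control."""

import numpy as np
import pandas as pd
import pytest

from tribp.evaluate import metrics
from tribp.modeling import (ModelSpec, SplitPlan, feature_columns,
                            fit_gbm, fit_linear_univariate, lasso_select,
                            predict, run_protocol)


def make_X(n=200, p=8, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"f{i}" for i in range(p)])
    return X, rng


class TestLassoSelect:
    def test_single_informative_column_selected(self):
        X, rng = make_X()
        y = 5.0 * X["f3"].to_numpy() + 0.01 * rng.standard_normal(len(X))
        selected = lasso_select(X, y, alpha=0.1)
        assert "f3" in selected
        assert len(selected) <= 3

    def test_total_shrinkage_falls_back_with_warning(self):
        X, rng = make_X()
        y = X["f1"].to_numpy() + 0.1 * rng.standard_normal(len(X))
        with pytest.warns(UserWarning, match="zero"):
            selected = lasso_select(X, y, alpha=1e6)
        assert selected == ["f1"]

    def test_duplicate_column_not_selected_twice(self):
        X, rng = make_X()
        X["dup"] = X["f2"]
        y = 3.0 * X["f2"].to_numpy() + 0.01 * rng.standard_normal(len(X))
        selected = lasso_select(X, y, alpha=0.1)
        assert len({"f2", "dup"} & set(selected)) >= 1
        # L1 on perfectly collinear pair keeps the weight on at most... both
        # may be kept by coordinate descent; the guarantee is no blow-up:
        assert len(selected) <= 4


class TestLinearUnivariate:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 1, 50)
        slope, intercept = fit_linear_univariate(x, 2.0 * x + 1.0)
        assert slope == pytest.approx(2.0, abs=1e-10)
        assert intercept == pytest.approx(1.0, abs=1e-10)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_linear_univariate(np.ones(10), np.arange(10.0))

    def test_ptt_sbp_coupling_recovered_without_wander(self):
        """With vasomotor wander off, the PTT-SBP slope is identifiable."""
        import dataclasses
        from tribp.pipeline import cohort_features
        from tribp.synth import NoiseConfig, SynthConfig, TimingWander
        from tests.conftest import compact_plan

        cfg = SynthConfig(
            n_subjects=2, phase_plan=compact_plan(), seed=21,
            noise=NoiseConfig.silent(),
            wander=TimingWander(0.0, 0.0, 0.0, 0.0), rr_jitter=0.0,
            minute_bp_sd=0.0,
        )
        feats = cohort_features(cfg)
        # per subject: SBP = sbp0 + (1/ptt_slope)·(PTT − ptt0_subj)
        for _, sub in feats.groupby("subject"):
            slope, _ = fit_linear_univariate(sub["ptt"].to_numpy(),
                                             sub["sbp"].to_numpy())
            expected = 1.0 / cfg.coupling.ptt_slope
            assert slope == pytest.approx(expected, rel=0.10)


class TestGBM:
    def test_fits_training_data_tightly(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 5))
        y = 100 + 10 * X[:, 0] - 5 * X[:, 2]
        model = fit_gbm(X, y, ModelSpec("ms-pwa", "sbp"))
        assert metrics(predict(model, X), y).mae < 1.0

    def test_permuted_labels_give_null_correlation(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((400, 5))
        y = 100 + 10 * X[:, 0]
        y_perm = rng.permutation(y[:200])
        model = fit_gbm(X[:200], y_perm, ModelSpec("ms-pwa", "sbp"))
        pcc = metrics(predict(model, X[200:]), y[200:]).pcc
        assert abs(pcc) < 0.2

    def test_same_seed_reproduces_predictions(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 4))
        y = rng.standard_normal(60)
        spec = ModelSpec("ms-pwa", "sbp", seed=9)
        p1 = predict(fit_gbm(X, y, spec), X)
        p2 = predict(fit_gbm(X, y, spec), X)
        np.testing.assert_array_equal(p1, p2)

    def test_non_finite_inputs_rejected(self):
        X = np.asarray([[1.0, np.nan]] * 25)
        with pytest.raises(ValueError, match="non-finite"):
            fit_gbm(X, np.zeros(25), ModelSpec("ms-pwa", "sbp"))


class TestRunProtocol:
    def test_predictions_only_for_test_stage(self, compact_features):
        preds = run_protocol(compact_features, ModelSpec("ms-pwa", "sbp"))
        assert set(preds["stage"]) == {4}
        n_stage4 = int((compact_features["stage"] == 4).sum())
        assert len(preds) == n_stage4

    def test_kfold_partitions_subjects_disjointly(self, compact_features):
        preds = run_protocol(compact_features, ModelSpec("ptt", "sbp"),
                             SplitPlan(mode="kfold", k=2, seed=0))
        # every subject appears exactly once in the pooled test predictions
        counts = preds.groupby("subject").size()
        per_subject = compact_features.groupby("subject").size()
        assert (counts == per_subject.loc[counts.index]).all()

    def test_fused_model_beats_interval_only_model(self, compact_features):
        mae = {}
        for kind in ("ms-pwa", "ptt"):
            preds = run_protocol(compact_features, ModelSpec(kind, "sbp"))
            mae[kind] = metrics(preds["y_pred"].to_numpy(),
                                preds["y_true"].to_numpy()).mae
        assert mae["ms-pwa"] < mae["ptt"]

    def test_leakage_canary_does_not_improve_test_error(self, compact_features):
        """A feature equal to y on test rows must not leak into training."""
        base = run_protocol(compact_features, ModelSpec("ms-pwa", "sbp"))
        mae_base = metrics(base["y_pred"].to_numpy(),
                           base["y_true"].to_numpy()).mae
        rigged = compact_features.copy()
        rng = np.random.default_rng(0)
        canary = np.where(rigged["stage"] == 4, rigged["sbp"],
                          rng.standard_normal(len(rigged)))
        rigged["ppg_pa"] = canary  # overwrite one fused-model column
        leaked = run_protocol(rigged, ModelSpec("ms-pwa", "sbp"))
        mae_leak = metrics(leaked["y_pred"].to_numpy(),
                           leaked["y_true"].to_numpy()).mae
        assert mae_leak >= mae_base - 0.5

    def test_unknown_kind_rejected(self, compact_features):
        with pytest.raises(ValueError, match="kind"):
            run_protocol(compact_features, ModelSpec("deep-net", "sbp"))

    def test_feature_columns_cardinality(self):
        assert feature_columns("pat") == ["pat"]
        assert len(feature_columns("ppg-pwa")) == 88
        assert len(feature_columns("icg-pwa")) == 66
        assert len(feature_columns("ms-pwa")) == 154
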