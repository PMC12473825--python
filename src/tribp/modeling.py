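"""LASSO feature selection and the five blood-pressure regression models.

Model kinds:

* ``pat`` / ``ptt`` — univariate ordinary-least-squares regression on the
  segment-mean pulse arrival time or pulse transit time;
* ``ppg-pwa`` / ``icg-pwa`` / ``ms-pwa`` — gradient-boosted regression
  trees (XGBoost) on the 88 PPG, 66 ICG, or fused 154 pulse-wave-analysis
  features, after LASSO (α = 0.1) selection on standardized training data.

Two evaluation splits are supported, mirroring the acquisition protocol:
the per-subject phase split (stages 1–3 train one personalized model per
subject, stage 4 tests it) and subject-independent k-fold cross-validation
(subjects partitioned into folds; one pooled model per fold).

Standardization and LASSO statistics are always fit on training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

from .features import all_feature_names, icg_feature_names, ppg_feature_names

__all__ = [
    "MODEL_KINDS",
    "TARGETS",
    "ModelSpec",
    "SplitPlan",
    "feature_columns",
    "lasso_select",
    "fit_linear_univariate",
    "fit_gbm",
    "predict",
    "run_protocol",
]

MODEL_KINDS = ("pat", "ptt", "ppg-pwa", "icg-pwa", "ms-pwa")
TARGETS = ("sbp", "dbp")
TRAIN_STAGES = (1, 2, 3)
TEST_STAGE = 4


@dataclass(frozen=True)
class ModelSpec:
    kind: str
    target: str
    lasso_alpha: float = 0.1
    n_rounds: int = 300
    max_depth: int = 4
    learning_rate: float = 0.05
    subsample: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; "
                             f"expected one of {MODEL_KINDS}")
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")


@dataclass(frozen=True)
class SplitPlan:
    """per-subject: stages 1-3 train / stage 4 test; kfold: split by subject."""

    mode: str = "per-subject"
    k: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("per-subject", "kfold"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")


def feature_columns(kind: str) -> list[str]:
    """Feature set used by each model kind."""
    if kind == "pat":
        return ["pat"]
    if kind == "ptt":
        return ["ptt"]
    if kind == "ppg-pwa":
        return ppg_feature_names()
    if kind == "icg-pwa":
        return icg_feature_names()
    if kind == "ms-pwa":
        return all_feature_names()
    raise ValueError(f"unknown model kind {kind!r}")


def lasso_select(X: pd.DataFrame, y: np.ndarray,
                 alpha: float = 0.1) -> list[str]:
    """Names of features with nonzero LASSO coefficients.

    Columns are standardized (zero mean, unit variance, fit on the given
    rows — callers must pass training rows only).  If the penalty shrinks
    every coefficient to zero, the single feature with the highest absolute
    Pearson correlation with y is returned instead, with a warning.
    """
    y = np.asarray(y, dtype=float)
    scaler = StandardScaler()
    Xs = scaler.fit_transform(X.to_numpy(dtype=float))
    Xs = np.nan_to_num(Xs)  # constant columns scale to 0, not NaN
    model = Lasso(alpha=alpha, max_iter=50_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, y)
    selected = [name for name, coef in zip(X.columns, model.coef_)
                if coef != 0.0]
    if not selected:
        warnings.warn("LASSO shrank all coefficients to zero; "
                      "falling back to the best-correlated feature",
                      stacklevel=2)
        yc = (y - y.mean())[:, None]
        sds = Xs.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cors = np.abs((Xs * yc).mean(axis=0)
                          / np.where(sds > 0, sds, np.nan)
                          / (y.std() if y.std() > 0 else np.nan))
        cors = np.nan_to_num(cors)
        selected = [X.columns[int(np.argmax(cors))]]
    return selected


def fit_linear_univariate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and intercept of y on a single feature."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("univariate fit needs at least two distinct x values")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def fit_gbm(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> XGBRegressor:
    """Seeded gradient-boosted regression trees on the selected features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in model inputs")
    model = XGBRegressor(
        n_estimators=spec.n_rounds,
        max_depth=spec.max_depth,
        learning_rate=spec.learning_rate,
        subsample=spec.subsample,
        random_state=spec.seed,
        tree_method="hist",
        n_jobs=1,
        verbosity=0,
    )
    model.fit(X, y)
    return model


def predict(model, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if isinstance(model, tuple):  # (slope, intercept) from the linear models
        slope, intercept = model
        return slope * X.ravel() + intercept
    return model.predict(X)


def _finite_rows(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    vals = df[cols].to_numpy(dtype=float)
    return df.loc[np.isfinite(vals).all(axis=1)]


def run_protocol(features: pd.DataFrame, spec: ModelSpec,
                 plan: SplitPlan | None = None) -> pd.DataFrame:
    """Train/evaluate one model kind under a split plan.

    Returns a predictions table with one row per test segment:
    subject, stage, label_index, window_index, y_true, y_pred, model, target.
    Segments with non-finite features are excluded; subjects missing the
    test stage are skipped (per-subject mode).
    """
    spec.validate()
    plan = plan or SplitPlan()
    plan.validate()
    cols = feature_columns(spec.kind)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing[:5]} ...")
    df = _finite_rows(features, cols + [spec.target])
    out_rows: list[pd.DataFrame] = []
    if plan.mode == "per-subject":
        train_all = df[df["stage"].isin(TRAIN_STAGES)]
        use_lasso = spec.kind in ("ppg-pwa", "icg-pwa", "ms-pwa")
        if use_lasso:
            selected = lasso_select(train_all[cols],
                                    train_all[spec.target].to_numpy(),
                                    alpha=spec.lasso_alpha)
        else:
            selected = cols
        for subject, sub in df.groupby("subject"):
            train = sub[sub["stage"].isin(TRAIN_STAGES)]
            test = sub[sub["stage"] == TEST_STAGE]
            if len(test) == 0 or len(train) < 10:
                continue
            y_tr = train[spec.target].to_numpy(dtype=float)
            if use_lasso:
                model = fit_gbm(train[selected].to_numpy(), y_tr, spec)
                y_hat = predict(model, test[selected].to_numpy())
            else:
                model = fit_linear_univariate(
                    train[selected[0]].to_numpy(), y_tr)
                y_hat = predict(model, test[selected[0]].to_numpy())
            out = test[["subject", "stage", "label_index",
                        "window_index"]].copy()
            out["y_true"] = test[spec.target].to_numpy(dtype=float)
            out["y_pred"] = y_hat
            out_rows.append(out)
    else:  # subject-independent k-fold
        subjects = np.asarray(sorted(df["subject"].unique()))
        rng = np.random.default_rng(plan.seed)
        perm = rng.permutation(len(subjects))
        folds = np.array_split(subjects[perm], plan.k)
        use_lasso = spec.kind in ("ppg-pwa", "icg-pwa", "ms-pwa")
        for fold in folds:
            test = df[df["subject"].isin(fold)]
            train = df[~df["subject"].isin(fold)]
            if len(test) == 0 or len(train) < 20:
                continue
            y_tr = train[spec.target].to_numpy(dtype=float)
            if use_lasso:
                selected = lasso_select(train[cols], y_tr,
                                        alpha=spec.lasso_alpha)
                model = fit_gbm(train[selected].to_numpy(), y_tr, spec)
                y_hat = predict(model, test[selected].to_numpy())
            else:
                model = fit_linear_univariate(train[cols[0]].to_numpy(), y_tr)
                y_hat = predict(model, test[cols[0]].to_numpy())
            out = test[["subject", "stage", "label_index",
                        "window_index"]].copy()
            out["y_true"] = test[spec.target].to_numpy(dtype=float)
            out["y_pred"] = y_hat
            out_rows.append(out)
    if not out_rows:
        raise ValueError("no test predictions produced (check stages/subjects)")
    pred = pd.concat(out_rows, ignore_index=True)
    pred["model"] = spec.kind
    pred["target"] = spec.target
    return pred
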