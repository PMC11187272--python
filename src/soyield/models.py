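"""The five yield regressors, the year-based train/test split, feature
normalization and tenfold cross-validation.

Models and hyperparameters (fixed, not re-searched):

* GBDT — gradient-boosted trees, learning rate 0.1, max depth 5, 800
  iterations, friedman_mse split criterion;
* CatBoost-style boosting — histogram-based gradient boosting, learning
  rate 0.05, max depth 10, 2000 iterations;
* LightGBM — learning rate 0.1, max tree depth 10;
* RF — random forest with 300 trees;
* MLP — two hidden layers (100, 50), relu, L2 0.01, adaptive learning
  rate, SGD solver, squared-error loss.

Features are z-scored with training-set statistics only; the test set is
transformed with the same scaler (no leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.ensemble import (
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .evaluation import metrics

MODEL_NAMES = ("catboost", "lightgbm", "gbdt", "rf", "mlp")

DEFAULT_SEED = 2022


@dataclass
class ModelSpec:
    """One regressor with its fixed hyperparameters."""

    name: str
    params: Dict = field(default_factory=dict)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")

    def build(self):
        p = dict(self.params)
        if self.name == "gbdt":
            # the tree splitter already uses friedman_mse; the constructor
            # argument is deprecated and a no-op in current scikit-learn
            p.pop("criterion", None)
            return GradientBoostingRegressor(random_state=self.seed, **p)
        if self.name == "catboost":
            return HistGradientBoostingRegressor(random_state=self.seed, **p)
        if self.name == "lightgbm":
            return LGBMRegressor(random_state=self.seed, n_jobs=1, verbose=-1, **p)
        if self.name == "rf":
            return RandomForestRegressor(random_state=self.seed, n_jobs=1, **p)
        if self.name == "mlp":
            return MLPRegressor(random_state=self.seed, **p)
        raise AssertionError(self.name)

    @property
    def supports_importance(self) -> bool:
        return self.name in ("gbdt", "rf", "lightgbm")


def default_specs(seed: int = DEFAULT_SEED) -> List[ModelSpec]:
    """The five model specs with their printed hyperparameters."""
    return [
        ModelSpec(
            "catboost",
            {"learning_rate": 0.05, "max_depth": 10, "max_iter": 2000},
            seed,
        ),
        ModelSpec("lightgbm", {"learning_rate": 0.1, "max_depth": 10}, seed),
        ModelSpec(
            "gbdt",
            {
                "learning_rate": 0.1,
                "max_depth": 5,
                "n_estimators": 800,
                "criterion": "friedman_mse",
            },
            seed,
        ),
        ModelSpec("rf", {"n_estimators": 300}, seed),
        ModelSpec(
            "mlp",
            {
                "hidden_layer_sizes": (100, 50),
                "activation": "relu",
                "alpha": 0.01,
                "learning_rate": "adaptive",
                "solver": "sgd",
                "max_iter": 500,
            },
            seed,
        ),
    ]


def year_split(table: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split by year: earliest year → train, later year(s) → test."""
    years = sorted(table["year"].unique())
    if len(years) < 2:
        raise ValueError("year_split requires at least 2 distinct years")
    train = table[table["year"] == years[0]].reset_index(drop=True)
    test = table[table["year"] != years[0]].reset_index(drop=True)
    if len(test) == 0 or len(train) == 0:
        raise ValueError("empty train or test year")
    return train, test


@dataclass
class ScalerRecord:
    mean: pd.Series
    sd: pd.Series
    zero_variance: List[str]


def normalize_features(
    train: pd.DataFrame,
    test: Optional[pd.DataFrame],
    feature_cols: Sequence[str],
) -> Tuple[pd.DataFrame, Optional[pd.DataFrame], ScalerRecord]:
    """Z-score features with training statistics only.

    Zero-variance training features are mapped to 0 everywhere and flagged
    in the returned scaler record.
    """
    if len(train) == 0:
        raise ValueError("empty training table")
    mu = train[list(feature_cols)].mean()
    sd = train[list(feature_cols)].std(ddof=0)
    zero_var = [c for c in feature_cols if sd[c] == 0]
    sd_safe = sd.replace(0, 1.0)

    def _apply(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out[list(feature_cols)] = (df[list(feature_cols)] - mu) / sd_safe
        out[zero_var] = 0.0
        return out

    return (
        _apply(train),
        _apply(test) if test is not None else None,
        ScalerRecord(mean=mu, sd=sd, zero_variance=zero_var),
    )


@dataclass
class FitResult:
    spec: ModelSpec
    feature_cols: List[str]
    train_pred: np.ndarray
    test_pred: np.ndarray
    train_metrics: Dict[str, float]
    test_metrics: Dict[str, float]
    importances: Optional[pd.Series] = None
    model: object = None


def fit_predict(
    spec: ModelSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_cols: Sequence[str],
    target_col: str = "yield_g",
    normalize: bool = True,
) -> FitResult:
    """Fit one spec on the training table and evaluate on both sets."""
    feature_cols = list(feature_cols)
    for df, label in ((train, "train"), (test, "test")):
        missing = [c for c in feature_cols if c not in df.columns]
        if missing:
            raise ValueError(f"{label} table lacks features {missing}")
        if df[feature_cols].isna().any().any():
            raise ValueError(f"NaN features in {label} table")
    if len(train) == 0 or len(test) == 0:
        raise ValueError("empty train or test set")

    if normalize:
        train_s, test_s, _ = normalize_features(train, test, feature_cols)
    else:
        train_s, test_s = train, test
    Xtr = train_s[feature_cols].astype(np.float64)
    ytr = train[target_col].to_numpy(dtype=np.float64)
    Xte = test_s[feature_cols].astype(np.float64)
    yte = test[target_col].to_numpy(dtype=np.float64)

    model = spec.build()
    model.fit(Xtr, ytr)
    pred_tr = np.asarray(model.predict(Xtr), dtype=np.float64)
    pred_te = np.asarray(model.predict(Xte), dtype=np.float64)

    imp = None
    if spec.supports_importance:
        raw = np.asarray(model.feature_importances_, dtype=np.float64)
        if raw.sum() > 0:
            raw = raw / raw.sum()
        imp = pd.Series(raw, index=feature_cols)

    return FitResult(
        spec=spec,
        feature_cols=feature_cols,
        train_pred=pred_tr,
        test_pred=pred_te,
        train_metrics=metrics(ytr, pred_tr),
        test_metrics=metrics(yte, pred_te),
        importances=imp,
        model=model,
    )


def cross_validate(
    spec: ModelSpec,
    table: pd.DataFrame,
    feature_cols: Sequence[str],
    target_col: str = "yield_g",
    k: int = 10,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Shuffled k-fold CV; per-fold RMSE/MAE/R² (NaN R² for 1-row folds)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(table) < k:
        raise ValueError("fewer rows than folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    idx = np.arange(len(table))
    for fold, (tr, te) in enumerate(kf.split(idx), start=1):
        train = table.iloc[tr].reset_index(drop=True)
        test = table.iloc[te].reset_index(drop=True)
        degenerate = len(test) < 2 or test[target_col].nunique() < 2
        if degenerate:
            train_s, test_s, _ = normalize_features(train, test, feature_cols)
            model = spec.build()
            model.fit(
                train_s[list(feature_cols)].to_numpy(np.float64),
                train[target_col].to_numpy(np.float64),
            )
            pred = np.asarray(model.predict(test_s[list(feature_cols)].to_numpy(np.float64)))
            yte = test[target_col].to_numpy(np.float64)
            row = {
                "fold": fold,
                "n_test": len(test),
                "RMSE": float(np.sqrt(np.mean((yte - pred) ** 2))),
                "MAE": float(np.mean(np.abs(yte - pred))),
                "R2": np.nan,
                "degenerate": True,
            }
        else:
            fr = fit_predict(spec, train, test, feature_cols, target_col)
            row = {
                "fold": fold,
                "n_test": len(test),
                "RMSE": fr.test_metrics["RMSE"],
                "MAE": fr.test_metrics["MAE"],
                "R2": fr.test_metrics["R2"],
                "degenerate": False,
            }
        rows.append(row)
    return pd.DataFrame(rows)
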