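"""Random-forest ddG regression with leave-complex-out cross-validation.

The regressor maps the 143-element mutation descriptor to the binding
free energy change ddG (kcal/mol) of the alanine mutation. Sparse
features are filtered first: a feature is retained only when it is
non-zero in more than 3 training mutations. The forest uses 500 trees
and a minimum terminal-node size of 3 mutations; the number of features
tried per split follows the regression convention of one third of the
retained features.

Cross-validation is grouped by complex: every mutation of one complex
forms a test fold while the forest trains on all other complexes, so no
information about a complex's interface leaks into its own predictions.
Feature filtering is re-run inside each training fold for the same
reason.

Feature importance is the %IncMSE permutation score: the percent
increase of the out-of-bag mean squared error after permuting one
feature's values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .config import RunConfig
from .contact_features import FEATURE_NAMES

try:  # out-of-bag bookkeeping helpers (fall back to in-sample permutation)
    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    _HAVE_OOB_HELPERS = True
except ImportError:  # pragma: no cover - depends on sklearn version
    _HAVE_OOB_HELPERS = False

__all__ = [
    "HotspotModel",
    "filter_features",
    "train",
    "predict",
    "loco_cv",
    "permutation_importance",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

ID_COLUMNS = ["complex_id", "chain", "seq_number", "wt_res"]


def _feature_columns(dataset: pd.DataFrame) -> List[str]:
    return [c for c in FEATURE_NAMES if c in dataset.columns]


@dataclass
class HotspotModel:
    """Trained forest plus its retained-feature schema and parameters."""

    forest: RandomForestRegressor
    features: List[str]
    n_trees: int
    min_node_size: int
    seed: int

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("model retains no features")


def filter_features(
    dataset: pd.DataFrame,
    min_nonzero: int = 3,
    columns: Optional[Sequence[str]] = None,
) -> List[str]:
    """Features non-zero in MORE than ``min_nonzero`` rows (strict)."""
    if len(dataset) < 1:
        raise ValueError("empty dataset")
    columns = list(columns) if columns is not None else _feature_columns(dataset)
    if not columns:
        raise ValueError("dataset has no feature columns")
    counts = (dataset[columns] != 0).sum(axis=0)
    kept = [c for c in columns if counts[c] > min_nonzero]
    if not kept:
        raise ValueError("no features retained by the non-zero filter")
    return kept


def _make_forest(cfg: RunConfig, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=cfg.n_trees,
        min_samples_leaf=cfg.min_node_size,
        max_features=cfg.max_features_frac,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def train(
    dataset: pd.DataFrame,
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
) -> HotspotModel:
    """Fit the ddG regression forest on a feature table.

    ``dataset`` needs one row per mutation with the feature columns, a
    ``complex_id`` and a numeric ``ddg_obs``. Deterministic given the
    seed.
    """
    cfg = config or RunConfig()
    seed = cfg.seed if seed is None else seed
    if len(dataset) < 10:
        raise ValueError(f"need at least 10 mutations to train, got {len(dataset)}")
    y = dataset["ddg_obs"].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError("ddg_obs is constant; nothing to learn")
    features = filter_features(dataset, cfg.min_nonzero)
    forest = _make_forest(cfg, seed)
    forest.fit(dataset[features].to_numpy(dtype=float), y)
    return HotspotModel(
        forest=forest,
        features=features,
        n_trees=cfg.n_trees,
        min_node_size=cfg.min_node_size,
        seed=seed,
    )


def predict(model: HotspotModel, features: pd.DataFrame) -> np.ndarray:
    """Ensemble-mean ddG predictions (kcal/mol) for a feature table."""
    missing = [c for c in model.features if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns of the model schema: {missing[:5]}")
    return model.forest.predict(features[model.features].to_numpy(dtype=float))


def loco_cv(
    dataset: pd.DataFrame,
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Leave-complex-out cross-validated predictions.

    Returns the dataset with a ``ddg_pred`` column; every row is
    predicted exactly once, by a model whose training fold excluded the
    row's complex. Feature filtering happens inside each training fold.
    """
    cfg = config or RunConfig()
    seed = cfg.seed if seed is None else seed
    complexes = list(dict.fromkeys(dataset["complex_id"]))
    if len(complexes) < 2:
        raise ValueError("leave-complex-out CV needs at least 2 complexes")
    out = dataset.copy()
    out["ddg_pred"] = np.nan
    for fold, complex_id in enumerate(complexes):
        test_mask = dataset["complex_id"] == complex_id
        train_rows = dataset.loc[~test_mask]
        model = train(train_rows, cfg, seed=seed + fold)
        out.loc[test_mask, "ddg_pred"] = predict(model, dataset.loc[test_mask])
    assert not out["ddg_pred"].isna().any()
    return out


def _oob_predictions(
    model: HotspotModel, X: np.ndarray
) -> Optional[Tuple[np.ndarray, np.ndarray]]:
    """Per-row OOB ensemble predictions (mean over trees not trained on the row)."""
    if not _HAVE_OOB_HELPERS:
        return None
    n = X.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n)
    n_boot = _get_n_samples_bootstrap(n, model.forest.max_samples, None)
    for tree in model.forest.estimators_:
        oob_idx = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if len(oob_idx) == 0:
            continue
        sums[oob_idx] += tree.predict(X[oob_idx])
        counts[oob_idx] += 1
    covered = counts > 0
    if not covered.any():
        return None
    preds = np.full(n, np.nan)
    preds[covered] = sums[covered] / counts[covered]
    return preds, covered


def permutation_importance(
    model: HotspotModel,
    dataset: pd.DataFrame,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """%IncMSE per retained feature.

    Mean over repeats of (MSE_permuted - MSE_baseline) / MSE_baseline *
    100, where both MSEs are out-of-bag on the training rows (falls back
    to in-sample MSE when OOB bookkeeping is unavailable). Larger scores
    mean the forest relied more on the feature.
    """
    rng = np.random.default_rng(seed)
    X = dataset[model.features].to_numpy(dtype=float)
    y = dataset["ddg_obs"].to_numpy(dtype=float)

    oob = _oob_predictions(model, X)

    def forest_mse(X_eval: np.ndarray) -> float:
        if oob is not None:
            _, covered = oob
            n = X_eval.shape[0]
            sums = np.zeros(n)
            counts = np.zeros(n)
            n_boot = _get_n_samples_bootstrap(n, model.forest.max_samples, None)
            for tree in model.forest.estimators_:
                oob_idx = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
                if len(oob_idx) == 0:
                    continue
                sums[oob_idx] += tree.predict(X_eval[oob_idx])
                counts[oob_idx] += 1
            mask = counts > 0
            preds = sums[mask] / counts[mask]
            return float(np.mean((preds - y[mask]) ** 2))
        preds = model.forest.predict(X_eval)
        return float(np.mean((preds - y) ** 2))

    mse_base = forest_mse(X)
    scores = np.zeros(len(model.features))
    for f_idx in range(len(model.features)):
        deltas = []
        for _ in range(n_repeats):
            X_perm = X.copy()
            X_perm[:, f_idx] = rng.permutation(X_perm[:, f_idx])
            deltas.append((forest_mse(X_perm) - mse_base) / mse_base * 100.0)
        scores[f_idx] = float(np.mean(deltas))
    return pd.Series(scores, index=model.features, name="pct_inc_mse").sort_values(
        ascending=False
    )


def save_model(model: HotspotModel, path: str) -> None:
    """Serialize the model with its schema and parameters."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "features": model.features,
            "n_trees": model.n_trees,
            "min_node_size": model.min_node_size,
            "seed": model.seed,
            "forest": model.forest,
        },
        path,
    )


def load_model(path: str) -> HotspotModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version: {payload.get('format_version')}")
    return HotspotModel(
        forest=payload["forest"],
        features=payload["features"],
        n_trees=payload["n_trees"],
        min_node_size=payload["min_node_size"],
        seed=payload["seed"],
    )
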