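"""Gradient-boosted ASE predictor with nested cross-validation.

The predictor is trained the way reproducible tabular-genomics models
are benchmarked: a stratified holdout (default 10%) is set aside first;
the remainder enters a nested cross-validation with a 10-fold outer loop
for performance estimation and a 6-fold inner loop for hyperparameter
selection by mean AUROC.  One gradient-boosting model with
``n_boost_iterations`` trees is fitted per outer fold; predictions on
new data average the outer-fold models' probabilities, and Gini
(impurity) feature importances are recorded per fold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from .evaluation import roc_auc
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

ENSEMBLE_FORMAT_VERSION = "asepred-ensemble-1"


@dataclass
class TrainConfig:
    """Nested cross-validation settings for the boosted-tree predictor.

    The hyperparameter grid defaults to the single library-default point
    (learning rate 0.1, tree depth 3), in which case the inner loop is a
    no-op selection; supplying several grid values activates inner-fold
    selection by mean AUROC.
    """

    n_boost_iterations: int = 100
    outer_folds: int = 10
    inner_folds: int = 6
    holdout_fraction: float = 0.10
    probability_threshold: float = 0.5
    hyperparameter_grid: dict = field(
        default_factory=lambda: {"learning_rate": [0.1], "max_depth": [3]})
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")
        if not (0.0 < self.holdout_fraction < 0.5):
            raise ValueError("holdout_fraction must lie in (0, 0.5)")
        if not (0.0 < self.probability_threshold < 1.0):
            raise ValueError("probability_threshold must lie in (0, 1)")

    def grid_points(self) -> list[dict]:
        keys = sorted(self.hyperparameter_grid)
        return [dict(zip(keys, vals)) for vals in
                itertools.product(*(self.hyperparameter_grid[k] for k in keys))]


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, FeatureMatrix):
        return matrix.values
    return matrix


def split_holdout(matrix, labels, fraction: float = 0.10, seed: int = 0):
    """Stratified holdout split; returns ((X_train, y_train), (X_test, y_test))."""
    X = _as_frame(matrix)
    y = pd.Series(np.asarray(labels).astype(int), index=X.index)
    if y.nunique() < 2:
        raise ValueError("both classes must be present to stratify the holdout")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=fraction, stratify=y, random_state=seed)
    return (X_tr, y_tr), (X_te, y_te)


class TrainedEnsemble:
    """Results object: the outer-fold models plus importances and diagnostics."""

    def __init__(self, models, feature_names, importances, outer_aurocs,
                 best_params, config, encoding=None):
        if importances.shape != (len(feature_names), len(models)):
            raise ValueError("importances must be (n_features, n_folds)")
        self.models = models
        self.feature_names = list(feature_names)
        self.importances = importances          # columns are outer folds, each sums to 1
        self.outer_aurocs = list(outer_aurocs)  # outer-validation AUROC per fold
        self.best_params = best_params
        self.config = config
        self.encoding = encoding
        self.version = ENSEMBLE_FORMAT_VERSION

    @property
    def n_folds(self) -> int:
        return len(self.models)

    def _check_columns(self, X: pd.DataFrame) -> None:
        if list(X.columns) != self.feature_names:
            missing = [c for c in self.feature_names if c not in X.columns]
            extra = [c for c in X.columns if c not in self.feature_names]
            raise ValueError(
                f"feature columns do not match training (missing={missing}, "
                f"extra={extra}, order must also match)")

    def predict_proba_per_fold(self, matrix) -> np.ndarray:
        """(n_rows, n_folds) array of each fold model's ASE probability."""
        X = _as_frame(matrix)
        self._check_columns(X)
        return np.column_stack([m.predict_proba(X.to_numpy())[:, 1] for m in self.models])

    def predict_proba(self, matrix) -> np.ndarray:
        """Ensemble probability: arithmetic mean over the outer-fold models."""
        return self.predict_proba_per_fold(matrix).mean(axis=1)

    def feature_importance(self) -> pd.DataFrame:
        """Per-feature mean and quartiles of Gini importance across folds."""
        imp = self.importances
        df = pd.DataFrame({
            "feature": self.feature_names,
            "importance_mean": imp.mean(axis=1),
            "importance_q1": np.percentile(imp, 25, axis=1),
            "importance_median": np.percentile(imp, 50, axis=1),
            "importance_q3": np.percentile(imp, 75, axis=1),
        })
        return df.sort_values("importance_mean", ascending=False,
                              kind="mergesort").reset_index(drop=True)

    def summary(self) -> str:
        top = self.feature_importance().head(5)
        lines = [
            "Gradient-boosted ASE predictor",
            "==============================",
            f"outer folds: {self.n_folds}   trees per model: "
            f"{self.config.n_boost_iterations}",
            f"selected hyperparameters: {self.best_params}",
            f"outer-validation AUROC: {np.mean(self.outer_aurocs):.3f} "
            f"+/- {np.std(self.outer_aurocs):.3f}",
            "top features (mean Gini importance):",
        ]
        for _, row in top.iterrows():
            lines.append(f"  {row['feature']:<24s} {row['importance_mean']:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        joblib.dump({
            "version": self.version, "models": self.models,
            "feature_names": self.feature_names, "importances": self.importances,
            "outer_aurocs": self.outer_aurocs, "best_params": self.best_params,
            "config": self.config, "encoding": self.encoding}, path)

    @classmethod
    def load(cls, path) -> "TrainedEnsemble":
        blob = joblib.load(path)
        if blob.get("version") != ENSEMBLE_FORMAT_VERSION:
            raise ValueError(f"unsupported model archive version {blob.get('version')!r}")
        return cls(blob["models"], blob["feature_names"], blob["importances"],
                   blob["outer_aurocs"], blob["best_params"], blob["config"],
                   blob["encoding"])


class AsePredictor:
    """Model object binding a numeric feature matrix to binary ASE labels.

    ``fit()`` runs the nested cross-validation and returns a
    :class:`TrainedEnsemble`.
    """

    def __init__(self, matrix, labels, config: TrainConfig | None = None):
        X = _as_frame(matrix)
        if X.isna().any().any():
            raise ValueError("feature matrix contains missing values; impute first")
        y = np.asarray(labels).astype(int)
        if len(y) != len(X):
            raise ValueError("labels are not aligned with the matrix rows")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        self.X = X
        self.y = y
        self.config = config or TrainConfig()
        self.encoding = getattr(matrix, "encoding", None)

    def _check_fold_feasibility(self) -> None:
        cfg = self.config
        counts = np.bincount(self.y, minlength=2)
        need = cfg.outer_folds
        if len(cfg.grid_points()) > 1:
            need = cfg.outer_folds * cfg.inner_folds
        if counts.min() < need:
            raise ValueError(
                f"class counts {counts.tolist()} too small for {cfg.outer_folds} outer x "
                f"{cfg.inner_folds} inner folds; use fewer folds or more data")

    def _select_params(self, X: np.ndarray, y: np.ndarray, seed: int) -> dict:
        """Inner CV: pick the grid point with the best mean AUROC."""
        cfg = self.config
        points = self.config.grid_points()
        if len(points) == 1:
            return points[0]
        inner = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True, random_state=seed)
        best, best_score = points[0], -np.inf
        for params in points:
            scores = []
            for tr, va in inner.split(X, y):
                clf = GradientBoostingClassifier(
                    n_estimators=cfg.n_boost_iterations, random_state=seed, **params)
                clf.fit(X[tr], y[tr])
                scores.append(roc_auc(clf.predict_proba(X[va])[:, 1], y[va]))
            score = float(np.mean(scores))
            if score > best_score:
                best, best_score = params, score
        return best

    def fit(self) -> TrainedEnsemble:
        """Nested CV training; reproducible from (data, config, seed)."""
        self._check_fold_feasibility()
        cfg = self.config
        Xa, ya = self.X.to_numpy(), self.y
        outer = StratifiedKFold(n_splits=cfg.outer_folds, shuffle=True,
                                random_state=cfg.seed)
        models, importances, aurocs, chosen = [], [], [], []
        for f, (tr, va) in enumerate(outer.split(Xa, ya)):
            fold_seed = cfg.seed + 1000 * (f + 1)
            params = self._select_params(Xa[tr], ya[tr], fold_seed)
            clf = GradientBoostingClassifier(
                n_estimators=cfg.n_boost_iterations, random_state=fold_seed, **params)
            clf.fit(Xa[tr], ya[tr])
            models.append(clf)
            chosen.append(params)
            imp = clf.feature_importances_
            total = imp.sum()
            importances.append(imp / total if total > 0 else imp)
            aurocs.append(roc_auc(clf.predict_proba(Xa[va])[:, 1], ya[va]))
            logger.info("outer fold %d/%d: params=%s AUROC=%.3f",
                        f + 1, cfg.outer_folds, params, aurocs[-1])
        return TrainedEnsemble(
            models=models, feature_names=list(self.X.columns),
            importances=np.column_stack(importances), outer_aurocs=aurocs,
            best_params=chosen, config=cfg, encoding=self.encoding)


def train_nested_cv(matrix, labels, config: TrainConfig | None = None) -> TrainedEnsemble:
    """Functional wrapper around :class:`AsePredictor`."""
    return AsePredictor(matrix, labels, config).fit()


def predict_proba(ensemble: TrainedEnsemble, matrix) -> np.ndarray:
    return ensemble.predict_proba(matrix)


def feature_importance(ensemble: TrainedEnsemble) -> pd.DataFrame:
    return ensemble.feature_importance()
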