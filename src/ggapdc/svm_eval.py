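"""RBF-kernel SVM training, grid search, and cross-validated evaluation.

The classifier is a support vector machine with a radial basis function
kernel; the regularization parameter C and the kernel width gamma are
optimized by grid search over the canonical libsvm-guide exponential grid,
scored by cross-validated overall accuracy.

Performance is summarized by sensitivity, specificity and overall accuracy
computed from pooled confusion counts:

    Sn = n+ / N+,   Sp = n- / N-,   OA = (n+ + n-) / (N+ + N-),

where n+ / n- are the correctly identified positive / negative samples and
N+ / N- the class totals. Cross-validation is stratified k-fold with seeded
shuffling; the jackknife (leave-one-out) variant is deterministic and
seed-independent.

Compositional features already live on a common [0, 1] scale, so no feature
scaling is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC

from .exceptions import (
    ContractError,
    DataError,
    ModelFormatError,
    StratificationError,
)
from .features import FeatureMatrix

__all__ = [
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "COARSE_C_GRID",
    "COARSE_GAMMA_GRID",
    "SVMConfig",
    "MetricsReport",
    "TrainedModel",
    "stratified_folds",
    "train_svm",
    "cross_validate",
    "grid_search_svm",
    "jackknife",
    "evaluate_subset",
    "save_model",
    "load_model",
]

#: Canonical libsvm-guide grid: C = 2^-5, 2^-3, ..., 2^15; gamma = 2^-15, ..., 2^3.
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** k for k in range(-15, 4, 2))

#: Coarse 3x3 grid used when hyperparameters are re-optimized many times.
COARSE_C_GRID: tuple[float, ...] = (2.0 ** -1, 2.0 ** 3, 2.0 ** 7)
COARSE_GAMMA_GRID: tuple[float, ...] = (2.0 ** -7, 2.0 ** -3, 2.0 ** 1)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameters and cross-validation settings.

    ``C``/``gamma`` are the chosen operating point (None until a grid search
    has picked them); ``c_grid``/``gamma_grid`` are the candidate values.
    """

    C: float | None = None
    gamma: float | None = None
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.c_grid or not self.gamma_grid:
            raise ContractError("hyperparameter grids must be non-empty")
        if self.folds < 2:
            raise ContractError(f"folds must be >= 2, got {self.folds}")
        if self.C is not None and self.C <= 0:
            raise ContractError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ContractError("gamma must be positive")

    def with_params(self, C: float, gamma: float) -> "SVMConfig":
        return replace(self, C=C, gamma=gamma)


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the Sn/Sp/OA they determine."""

    n_pos_correct: int
    n_neg_correct: int
    n_pos_total: int
    n_neg_total: int

    def __post_init__(self):
        if not (0 <= self.n_pos_correct <= self.n_pos_total):
            raise ContractError("0 <= n+ <= N+ violated")
        if not (0 <= self.n_neg_correct <= self.n_neg_total):
            raise ContractError("0 <= n- <= N- violated")

    @property
    def sn(self) -> float:
        return self.n_pos_correct / self.n_pos_total

    @property
    def sp(self) -> float:
        return self.n_neg_correct / self.n_neg_total

    @property
    def oa(self) -> float:
        return (self.n_pos_correct + self.n_neg_correct) / (
            self.n_pos_total + self.n_neg_total
        )

    def to_dict(self) -> dict:
        return {
            "n_pos_correct": self.n_pos_correct,
            "n_neg_correct": self.n_neg_correct,
            "n_pos_total": self.n_pos_total,
            "n_neg_total": self.n_neg_total,
            "Sn": self.sn,
            "Sp": self.sp,
            "OA": self.oa,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class TrainedModel:
    """A fitted SVM plus the feature contract it was trained under."""

    svc: SVC
    n_features: int
    g: int
    feature_indices: np.ndarray | None = None
    denominator: str = "positions"
    C: float = 1.0
    gamma: float = 1.0

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ContractError(
                f"model expects {self.n_features} features, got {X.shape[1]}"
            )
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self._check(X))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._check(X))


def train_svm(
    X: np.ndarray | FeatureMatrix,
    y: np.ndarray | None = None,
    C: float = 1.0,
    gamma: float = 1.0,
    *,
    g: int = 0,
    feature_indices: Sequence[int] | None = None,
) -> TrainedModel:
    """Fit an RBF SVM on a labelled matrix (both classes required)."""
    if isinstance(X, FeatureMatrix):
        matrix = X
        y = matrix.y
        g = matrix.g
        X = matrix.X
        if feature_indices is not None:
            X = X[:, np.asarray(feature_indices, dtype=int)]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise DataError("training requires samples from both classes")
    svc = SVC(C=C, gamma=gamma, kernel="rbf")
    svc.fit(X, y)
    return TrainedModel(
        svc=svc,
        n_features=X.shape[1],
        g=g,
        feature_indices=None if feature_indices is None
        else np.asarray(feature_indices, dtype=int),
        C=C,
        gamma=gamma,
    )


def stratified_folds(
    y: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold split with seeded shuffling.

    Each fold's class fraction is within one sample of the global fraction.
    Raises :class:`StratificationError` if k exceeds the size of the
    smaller class (a fold would then miss a class).
    """
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both classes must be present for stratified folds")
    if k > counts.min():
        raise StratificationError(
            f"k={k} folds infeasible: smallest class has {counts.min()} samples"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((len(y), 1)), y))


def _pooled_cv_counts(
    X: np.ndarray,
    y: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    C: float,
    gamma: float,
) -> MetricsReport:
    n_pos_correct = n_neg_correct = 0
    for train_idx, test_idx in folds:
        y_train = y[train_idx]
        if len(np.unique(y_train)) < 2:
            raise StratificationError("a training fold is missing one class")
        svc = SVC(C=C, gamma=gamma, kernel="rbf")
        svc.fit(X[train_idx], y_train)
        pred = svc.predict(X[test_idx])
        truth = y[test_idx]
        n_pos_correct += int(np.sum((truth == 1) & (pred == 1)))
        n_neg_correct += int(np.sum((truth == 0) & (pred == 0)))
    return MetricsReport(
        n_pos_correct=n_pos_correct,
        n_neg_correct=n_neg_correct,
        n_pos_total=int(np.sum(y == 1)),
        n_neg_total=int(np.sum(y == 0)),
    )


def cross_validate(
    matrix: FeatureMatrix,
    config: SVMConfig,
    *,
    feature_indices: Sequence[int] | None = None,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation at the config's (C, gamma).

    Every sample is predicted exactly once by a model not trained on it;
    confusion counts are pooled over folds. Deterministic given
    ``config.seed``. Precomputed ``folds`` may be passed to share a split
    across several evaluations.
    """
    if config.C is None or config.gamma is None:
        raise ContractError("config.C and config.gamma must be set (run grid search)")
    X = matrix.X
    if feature_indices is not None:
        X = X[:, np.asarray(feature_indices, dtype=int)]
    if folds is None:
        folds = stratified_folds(matrix.y, config.folds, config.seed)
    return _pooled_cv_counts(X, matrix.y, folds, config.C, config.gamma)


def grid_search_svm(
    matrix: FeatureMatrix,
    config: SVMConfig,
    *,
    feature_indices: Sequence[int] | None = None,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[float, float]:
    """Pick the (C, gamma) grid point maximizing cross-validated OA.

    All grid points are scored on the same seeded fold split. Ties are
    broken toward smaller C, then smaller gamma, by scanning the grid in
    ascending order and keeping only strict improvements.
    """
    X = matrix.X
    if feature_indices is not None:
        X = X[:, np.asarray(feature_indices, dtype=int)]
    if folds is None:
        folds = stratified_folds(matrix.y, config.folds, config.seed)
    best: tuple[float, float] | None = None
    best_oa = -1.0
    for C in sorted(config.c_grid):
        for gamma in sorted(config.gamma_grid):
            oa = _pooled_cv_counts(X, matrix.y, folds, C, gamma).oa
            if oa > best_oa:
                best_oa = oa
                best = (C, gamma)
    assert best is not None
    return best


def jackknife(
    matrix: FeatureMatrix,
    config: SVMConfig,
    *,
    feature_indices: Sequence[int] | None = None,
) -> MetricsReport:
    """Leave-one-out cross-validation: deterministic, seed-independent.

    Each of the N+ + N- samples is predicted by a model trained on all the
    others.
    """
    if config.C is None or config.gamma is None:
        raise ContractError("config.C and config.gamma must be set (run grid search)")
    if matrix.m_pos < 2 or matrix.m_neg < 2:
        raise DataError("jackknife needs at least 2 samples per class")
    X = matrix.X
    if feature_indices is not None:
        X = X[:, np.asarray(feature_indices, dtype=int)]
    folds = list(LeaveOneOut().split(X))
    return _pooled_cv_counts(X, matrix.y, folds, config.C, config.gamma)


def evaluate_subset(
    matrix: FeatureMatrix,
    feature_indices: Sequence[int],
    config: SVMConfig,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    hyper: str = "grid",
) -> MetricsReport:
    """Cross-validate a feature subset under a shared fold split.

    ``hyper="grid"`` re-optimizes (C, gamma) on the coarse grid for this
    subset; ``hyper="fixed"`` uses the (C, gamma) already set on the config.
    Shared by the incremental-feature-selection loop and the top-k model so
    the two agree pointwise.
    """
    if hyper == "grid":
        coarse = replace(config, c_grid=COARSE_C_GRID, gamma_grid=COARSE_GAMMA_GRID)
        C, gamma = grid_search_svm(
            matrix, coarse, feature_indices=feature_indices, folds=folds
        )
    elif hyper == "fixed":
        if config.C is None or config.gamma is None:
            raise ContractError("hyper='fixed' requires config.C and config.gamma")
        C, gamma = config.C, config.gamma
    else:
        raise ValueError(f"unknown hyper mode {hyper!r}; expected grid|fixed")
    X = matrix.X[:, np.asarray(feature_indices, dtype=int)]
    return _pooled_cv_counts(X, matrix.y, folds, C, gamma)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model with its feature contract, versioned."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "g": model.g,
        "n_features": model.n_features,
        "feature_indices": None if model.feature_indices is None
        else model.feature_indices.tolist(),
        "denominator": model.denominator,
        "C": model.C,
        "gamma": model.gamma,
        "svc": model.svc,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model archive, refusing incompatible format versions."""
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model archive {path} has format version {version!r}; "
            f"this build reads version {MODEL_FORMAT_VERSION}"
        )
    return TrainedModel(
        svc=payload["svc"],
        n_features=payload["n_features"],
        g=payload["g"],
        feature_indices=None if payload["feature_indices"] is None
        else np.asarray(payload["feature_indices"], dtype=int),
        denominator=payload["denominator"],
        C=payload["C"],
        gamma=payload["gamma"],
    )
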