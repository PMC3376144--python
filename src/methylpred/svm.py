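"""RBF-kernel support vector machine: training, tuning, persistence.

Class imbalance is handled upstream by negative subsampling, so the SVM
itself is trained unweighted.  The decision threshold is fixed at 0; raw
decision values are returned for downstream thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

MODEL_FORMAT_VERSION = 1

#: Canonical coarse grid: C = 2^-5, 2^-3, ..., 2^15; gamma = 2^-15, ..., 2^3.
DEFAULT_C_EXPONENTS = range(-5, 16, 2)
DEFAULT_GAMMA_EXPONENTS = range(-15, 4, 2)


class ModelError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class SvmHyperparams:
    """Penalty parameter C and RBF kernel width gamma, both > 0."""

    C: float = 8.0
    gamma: float = 2.0**-5

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ModelError(
                f"C and gamma must be strictly positive, got C={self.C}, "
                f"gamma={self.gamma}"
            )


def default_grid() -> list[SvmHyperparams]:
    return [
        SvmHyperparams(C=2.0**c, gamma=2.0**g)
        for c in DEFAULT_C_EXPONENTS
        for g in DEFAULT_GAMMA_EXPONENTS
    ]


@dataclass
class TrainedModel:
    """A fitted RBF-SVM plus the feature layout it is valid for."""

    hyperparams: SvmHyperparams
    layout: dict[str, tuple[int, int]]
    clf: SVC = field(repr=False)
    version: int = MODEL_FORMAT_VERSION

    @property
    def n_features(self) -> int:
        return max(end for _, end in self.layout.values())


def train(
    X: np.ndarray,
    y: np.ndarray,
    params: SvmHyperparams,
    layout: Optional[dict[str, tuple[int, int]]] = None,
) -> TrainedModel:
    """Fit the RBF-kernel SVM; deterministic given inputs and params."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ModelError("X must be 2-D with one label per row")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ModelError(
            f"training data must contain both classes, got only {classes}"
        )
    clf = SVC(kernel="rbf", C=params.C, gamma=params.gamma)
    clf.fit(X, y)
    if layout is None:
        layout = {"ALL": (0, X.shape[1])}
    return TrainedModel(hyperparams=params, layout=dict(layout), clf=clf)


def predict(
    model: TrainedModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels (1 = positive iff decision value > 0) and decision values."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(0, model.n_features) if X.size == 0 else X.reshape(1, -1)
    if X.shape[0] == 0:
        return np.empty(0, dtype=int), np.empty(0)
    if X.shape[1] != model.n_features:
        raise ModelError(
            f"feature layout mismatch: model expects {model.n_features} "
            f"features (layout {model.layout}), input has {X.shape[1]}"
        )
    scores = model.clf.decision_function(X)
    labels = (scores > 0).astype(int)
    return labels, scores


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: Optional[Sequence[SvmHyperparams]] = None,
    folds: int = 5,
    seed: int = 0,
) -> SvmHyperparams:
    """Pick the grid point maximizing mean stratified-CV accuracy.

    Exact ties are broken toward the smallest C, then smallest gamma.
    """
    from .evaluation import kfold_split  # deferred: evaluation imports svm

    if grid is None:
        grid = default_grid()
    if not grid:
        raise ModelError("hyperparameter grid is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    order = np.concatenate([np.flatnonzero(y == 1), np.flatnonzero(y == 0)])
    folds_idx = kfold_split(n_pos, n_neg, folds, seed)

    best: tuple[float, SvmHyperparams] | None = None
    for params in grid:
        correct = 0
        for fold in folds_idx:
            test_mask = np.zeros(len(y), dtype=bool)
            test_mask[order[fold]] = True
            model = train(X[~test_mask], y[~test_mask], params)
            labels, _ = predict(model, X[test_mask])
            correct += int(np.sum(labels == y[test_mask]))
        acc = correct / len(y)
        if best is None or acc > best[0] or (acc == best[0] and params < best[1]):
            best = (acc, params)
    return best[1]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist as a single-file bundle with a format version tag."""
    joblib.dump(
        {
            "format_version": model.version,
            "hyperparams": {"C": model.hyperparams.C, "gamma": model.hyperparams.gamma},
            "layout": model.layout,
            "clf": model.clf,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    bundle = joblib.load(path)
    version = bundle.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelError(
            f"model file format version {version} is incompatible with "
            f"this package (expects {MODEL_FORMAT_VERSION})"
        )
    return TrainedModel(
        hyperparams=SvmHyperparams(**bundle["hyperparams"]),
        layout=bundle["layout"],
        clf=bundle["clf"],
        version=version,
    )
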