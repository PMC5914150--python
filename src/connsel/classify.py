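"""RBF soft-margin SVM with leave-one-subject-out cross-validation.

The two task conditions are classified from regional graph-metric features.
Validation is leave-one-subject-out (LOSOCV): both samples of one subject
are held out together, the C-SVM is trained on all remaining subjects, and
accuracy is pooled over all held-out samples.  Features are z-scored with
mean and standard deviation estimated on the training folds only, so no
statistic of the held-out subject ever reaches training.

Hyperparameters (cost C and RBF width gamma) come from a grid search over
powers of two, the standard libsvm practice; the grid search criterion is
the LOSOCV accuracy itself.  Ties are broken toward the smallest C, then
the smallest gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

try:  # low-level libsvm binding: identical solver, far less call overhead
    from sklearn.svm._base import libsvm as _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - layout differs across versions
    _libsvm = None

from .graph_metrics import FeatureTable

__all__ = [
    "SvmHyperparams",
    "HyperGrid",
    "CVResult",
    "DegenerateMaskError",
    "losocv_accuracy",
    "grid_search",
]


class DegenerateMaskError(ValueError):
    """A selection mask with no active feature was supplied."""


@dataclass(frozen=True)
class SvmHyperparams:
    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError(f"C and gamma must be positive, got {self}")


@dataclass(frozen=True)
class HyperGrid:
    C_values: tuple[float, ...]
    gamma_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, vals in (("C", self.C_values), ("gamma", self.gamma_values)):
            v = tuple(float(x) for x in vals)
            object.__setattr__(self, f"{name}_values", v)
            if not v:
                raise ValueError(f"{name}_values must be non-empty")
            if any(b <= a for a, b in zip(v, v[1:])):
                raise ValueError(f"{name}_values must be strictly increasing")
            if v[0] <= 0:
                raise ValueError(f"{name}_values must be positive")

    @classmethod
    def default(cls) -> "HyperGrid":
        """C in 2^-5..2^15, gamma in 2^-15..2^3, both in steps of 2^2."""
        return cls(
            C_values=tuple(2.0**e for e in range(-5, 16, 2)),
            gamma_values=tuple(2.0**e for e in range(-15, 4, 2)),
        )

    @classmethod
    def coarse(cls) -> "HyperGrid":
        """Small 3x3 sub-grid used for cheap fitness evaluations."""
        return cls(
            C_values=(2.0**0, 2.0**4, 2.0**8),
            gamma_values=(2.0**-7, 2.0**-4, 2.0**-1),
        )

    @property
    def size(self) -> int:
        return len(self.C_values) * len(self.gamma_values)


@dataclass
class CVResult:
    """LOSOCV outcome: pooled accuracy, held-out predictions, chosen (C, gamma)."""

    accuracy: float
    per_fold_predictions: np.ndarray  # predicted label per sample, row-aligned
    hyperparams: SvmHyperparams
    true_labels: np.ndarray = field(default=None, repr=False)
    fold_train_rows: dict = field(default_factory=dict, repr=False)

    def recomputed_accuracy(self) -> float:
        return float(np.mean(self.per_fold_predictions == self.true_labels))


def _apply_mask(ft: FeatureTable, mask) -> np.ndarray:
    if mask is None:
        return ft.X
    bits = np.asarray(getattr(mask, "bits", mask)).astype(bool)
    if bits.shape != (ft.d,):
        raise ValueError(f"mask length {bits.size} does not match d={ft.d}")
    if not bits.any():
        raise DegenerateMaskError("selection mask has no active feature")
    return ft.X[:, bits]


def _losocv_prediction_grid(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    grid: HyperGrid,
) -> tuple[np.ndarray, dict]:
    """Held-out predictions for every (gamma, C) grid point.

    Returns preds of shape (n_gamma, n_C, n_samples) with encoded labels,
    plus a record of training-row indices per fold for leakage auditing.
    The RBF kernel is built once per fold and gamma on squared distances of
    fold-standardized features, then reused across all C values.
    """
    subjects = np.unique(groups)
    if subjects.size < 3:
        raise ValueError(f"LOSOCV needs >= 3 subjects, got {subjects.size}")
    classes, y_enc = np.unique(y, return_inverse=True)
    y_enc = y_enc.astype(np.float64)
    n = X.shape[0]
    n_g, n_c = len(grid.gamma_values), len(grid.C_values)
    preds = np.empty((n_g, n_c, n), dtype=np.float64)
    fold_record: dict = {}
    for s in subjects:
        test = groups == s
        train = ~test
        fold_record[s] = np.flatnonzero(train)
        y_tr = y_enc[train]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"training fold for held-out subject {s!r} is single-class")
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0  # constant feature carries no information; leave centred
        Xtr = (X[train] - mu) / sd
        Xte = (X[test] - mu) / sd
        sq_tr = np.einsum("ij,ij->i", Xtr, Xtr)
        sq_te = np.einsum("ij,ij->i", Xte, Xte)
        d2_tr = np.maximum(sq_tr[:, None] + sq_tr[None, :] - 2.0 * Xtr @ Xtr.T, 0.0)
        d2_te = np.maximum(sq_te[:, None] + sq_tr[None, :] - 2.0 * Xte @ Xtr.T, 0.0)
        for gi, gamma in enumerate(grid.gamma_values):
            K_tr = np.ascontiguousarray(np.exp(-gamma * d2_tr))
            K_te = np.ascontiguousarray(np.exp(-gamma * d2_te))
            for ci, C in enumerate(grid.C_values):
                preds[gi, ci, test] = _fit_predict(K_tr, y_tr, K_te, C)
    return classes[preds.astype(np.intp)], fold_record


def _fit_predict(K_tr: np.ndarray, y_tr: np.ndarray, K_te: np.ndarray, C: float):
    """One C-SVM fit + prediction on precomputed kernels (libsvm solver)."""
    if _libsvm is not None:
        m = _libsvm.fit(K_tr, y_tr, svm_type=0, kernel="precomputed", C=C)
        return _libsvm.predict(
            K_te, m[0], m[1], m[2], m[3], m[4], svm_type=0, kernel="precomputed"
        )
    clf = SVC(C=C, kernel="precomputed")
    clf.fit(K_tr, y_tr)
    return clf.predict(K_te)


def _best_grid_point(acc: np.ndarray, grid: HyperGrid) -> tuple[int, int]:
    """Argmax of acc[(gamma, C)] with ties toward smallest C, then gamma."""
    best = (-1.0, None)
    for ci in range(len(grid.C_values)):
        for gi in range(len(grid.gamma_values)):
            if acc[gi, ci] > best[0] + 1e-12:
                best = (acc[gi, ci], (gi, ci))
    return best[1]


def grid_search(
    ft: FeatureTable, mask=None, grid: HyperGrid | None = None
) -> CVResult:
    """LOSOCV accuracy maximized over the Cartesian (C, gamma) grid."""
    grid = grid or HyperGrid.default()
    X = _apply_mask(ft, mask)
    preds, folds = _losocv_prediction_grid(X, ft.labels, ft.groups, grid)
    acc = (preds == ft.labels[None, None, :]).mean(axis=2)
    gi, ci = _best_grid_point(acc, grid)
    return CVResult(
        accuracy=float(acc[gi, ci]),
        per_fold_predictions=preds[gi, ci].copy(),
        hyperparams=SvmHyperparams(grid.C_values[ci], grid.gamma_values[gi]),
        true_labels=ft.labels.copy(),
        fold_train_rows=folds,
    )


def losocv_accuracy(ft: FeatureTable, mask=None, hp: SvmHyperparams | None = None) -> CVResult:
    """LOSOCV at a single hyperparameter point (default C=1, gamma=1/m)."""
    X = _apply_mask(ft, mask)
    if hp is None:
        hp = SvmHyperparams(C=1.0, gamma=1.0 / X.shape[1])
    grid = HyperGrid(C_values=(hp.C,), gamma_values=(hp.gamma,))
    preds, folds = _losocv_prediction_grid(X, ft.labels, ft.groups, grid)
    acc = float((preds[0, 0] == ft.labels).mean())
    return CVResult(
        accuracy=acc,
        per_fold_predictions=preds[0, 0].copy(),
        hyperparams=hp,
        true_labels=ft.labels.copy(),
        fold_train_rows=folds,
    )
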