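"""Kernel SVM classification over feature matrices.

Four kernels are compared throughout: RBF, linear, polynomial and
quadratic (a polynomial kernel with the degree pinned to 2).  Features are
z-scored with training-set statistics before any kernel evaluation — the
13 features live on wildly different scales (contrast vs. smoothness), and
an RBF over raw columns would be dominated by the largest one.

The Gram matrices are computed here from the kernel formulas; the
soft-margin dual problem itself is solved by scikit-learn's SVC on the
precomputed Gram matrix (a standard QP, with the solution frozen into
:class:`TrainedKSVM` so the decision function is reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.svm import SVC

from lpbrain.features import FeatureMatrix

KERNEL_KINDS = ("linear", "rbf", "polynomial", "quadratic")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its hyperparameters.

    ``gamma=None`` means the median heuristic ``1 / (d * var(X))`` resolved
    from the training matrix at fit time (the 'scale' rule).
    ``quadratic`` is ``polynomial`` with degree fixed at 2.
    """

    kind: str = "rbf"
    gamma: float | None = None
    degree: int = 3
    coef0: float = 1.0
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kind must be one of {KERNEL_KINDS}, got {self.kind!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")

    @property
    def effective_degree(self) -> int:
        return 2 if self.kind == "quadratic" else self.degree


def resolve_gamma(spec: KernelSpec, X: np.ndarray) -> float:
    """The RBF bandwidth actually used: explicit gamma or 1/(d*var(X))."""
    if spec.gamma is not None:
        return spec.gamma
    var = float(np.asarray(X).var())
    return 1.0 / (X.shape[1] * var) if var > 0 else 1.0


def kernel_matrix(X: np.ndarray, Y: np.ndarray, spec: KernelSpec,
                  gamma: float | None = None) -> np.ndarray:
    """Gram matrix ``K[i, j] = k(X[i], Y[j])`` for the given kernel.

    linear: ``x . y``; rbf: ``exp(-gamma ||x - y||^2)``;
    polynomial/quadratic: ``(x . y + coef0)^degree``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if spec.kind == "linear":
        return X @ Y.T
    if spec.kind == "rbf":
        g = gamma if gamma is not None else resolve_gamma(spec, X)
        d2 = (np.sum(X ** 2, axis=1)[:, None] + np.sum(Y ** 2, axis=1)[None, :]
              - 2.0 * X @ Y.T)
        return np.exp(-g * np.maximum(d2, 0.0))
    # polynomial / quadratic
    return (X @ Y.T + spec.coef0) ** spec.effective_degree


@dataclass(frozen=True)
class TrainedKSVM:
    """A fitted kernel SVM: everything needed to reproduce decisions.

    Stores the z-scoring statistics, the (standardized) support vectors
    with their dual coefficients and bias, and the label ordering, so
    ``decision_function`` is a pure function of these fields.
    """

    spec: KernelSpec
    gamma: float
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.scaler_mean) / self.scaler_std

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = self._standardize(np.atleast_2d(X))
        K = kernel_matrix(Xs, self.support_vectors, self.spec, gamma=self.gamma)
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        # sklearn binary convention: positive score -> classes[1]
        return np.where(scores > 0, self.classes[1], self.classes[0])


def train_ksvm(F: FeatureMatrix, spec: KernelSpec = KernelSpec()) -> TrainedKSVM:
    """Fit a soft-margin binary kernel SVM on a feature matrix.

    Columns are z-scored with training statistics (zero-variance columns
    get unit scale); the dual problem is solved on the precomputed Gram
    matrix to tolerance 1e-4.
    """
    classes = tuple(sorted(set(F.labels)))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes to train, got {classes}")
    if len(classes) > 2:
        raise ValueError(f"binary classification only, got {classes}")
    mean = F.X.mean(axis=0)
    std = F.X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xs = (F.X - mean) / std
    y = np.array([classes.index(lab) for lab in F.labels])

    gamma = resolve_gamma(spec, Xs)
    K = kernel_matrix(Xs, Xs, spec, gamma=gamma)
    svc = SVC(kernel="precomputed", C=spec.C, tol=1e-4)
    svc.fit(K, y)

    sv_idx = svc.support_
    return TrainedKSVM(
        spec=spec,
        gamma=gamma,
        scaler_mean=mean,
        scaler_std=std,
        support_vectors=Xs[sv_idx],
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        classes=classes,
        feature_names=F.feature_names,
    )


def evaluate_accuracy(model: TrainedKSVM, F_val: FeatureMatrix) -> float:
    """Percent of validation rows classified correctly, in [0, 100]."""
    if F_val.feature_names != model.feature_names:
        raise ValueError(
            f"validation schema {F_val.feature_names} does not match the "
            f"trained model's {model.feature_names}")
    pred = model.predict(F_val.X)
    correct = sum(p == t for p, t in zip(pred, F_val.labels))
    return 100.0 * correct / F_val.n
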