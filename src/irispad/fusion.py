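"""Feature-level and score-level fusion of handcrafted and deep features.

Two subsystem combinations are supported:

* **Feature-level fusion** — each feature vector is z-score normalized
  with training-set statistics, ``f_norm = (f - f_mean) / sigma``; the
  normalized CNN and MLBP vectors are concatenated (CNN block first,
  4096 + 933 = 5029 dimensions for the full specs), reduced to 512
  principal components, and classified by one kernel SVM.

* **Score-level fusion** — each feature type drives its own z-score /
  PCA / kernel-SVM subsystem whose decision value is calibrated to an
  attack probability in [0, 1] (Platt-style logistic); the final score
  is the convex combination ``S = w1*S1 + w2*S2`` with ``w1 + w2 = 1``,
  the weights chosen by a grid search for best training accuracy at the
  0.5 threshold.

Kernels are the standard linear ``x_i . x_j``, RBF
``exp(-gamma*||x_i - x_j||^2)`` and polynomial
``(gamma * x_i . x_j + coef)^degree``.  The positive class is *attack*
throughout, so higher scores mean more attack-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from irispad.errors import TrainingError, ValidationError
from irispad.mlbp import FeatureVector

_SIGMA_FLOOR = 1e-8


@dataclass(frozen=True)
class NormStats:
    """Per-dimension training mean and standard deviation (population)."""

    f_mean: np.ndarray
    sigma: np.ndarray


def fit_norm(train_features: np.ndarray) -> NormStats:
    """Training-set z-score statistics.

    Dimensions with standard deviation below 1e-8 get sigma = 1, so the
    feature passes through centered (common with sparse LBP bins).
    """
    x = np.asarray(train_features, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("need >= 2 training vectors of equal dimension")
    mean = x.mean(axis=0)
    sigma = x.std(axis=0)  # population sd
    sigma = np.where(sigma < _SIGMA_FLOOR, 1.0, sigma)
    return NormStats(f_mean=mean, sigma=sigma)


def z_normalize(f: np.ndarray, stats: NormStats) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    return (f - stats.f_mean) / stats.sigma


def concat(f1_norm: np.ndarray, f2_norm: np.ndarray) -> FeatureVector:
    """Hybrid feature: CNN block first, MLBP block second."""
    values = np.concatenate(
        [np.atleast_1d(np.asarray(f1_norm)), np.atleast_1d(np.asarray(f2_norm))]
    )
    return FeatureVector(values=values, kind="hybrid")


@dataclass
class PcaModel:
    mean: np.ndarray
    components: np.ndarray  # (k, dim), rows orthonormal
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]


def default_pca_k(n_train: int, dim: int, k: int = 512) -> int:
    return min(k, n_train - 1, dim)


def fit_pca(train_features: np.ndarray, k: int) -> PcaModel:
    """Top-k variance-ordered orthonormal basis after mean-centering."""
    x = np.asarray(train_features, dtype=np.float64)
    if k > min(x.shape):
        raise ValidationError(
            f"k={k} exceeds min(n_train, dim)={min(x.shape)}"
        )
    model = PCA(n_components=k, svd_solver="full")
    model.fit(x)
    return PcaModel(
        mean=model.mean_,
        components=model.components_,
        explained_variance=model.explained_variance_,
    )


def project(f: np.ndarray, model: PcaModel) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    return (f - model.mean) @ model.components.T


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "rbf"  # linear | rbf | polynomial
    #: None -> variance-scaled default 1/(dim * Var(X)) at training time
    #: (1/dim for a standalone pair, where no training variance exists)
    gamma: float | None = None
    coef: float = 1.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf", "polynomial"):
            raise ValidationError(f"unknown kernel kind {self.kind!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValidationError("gamma must be positive")
        if self.degree < 1:
            raise ValidationError("degree must be >= 1")


def kernel(xi: np.ndarray, xj: np.ndarray, spec: KernelSpec) -> float:
    """Evaluate the kernel function on a pair of vectors."""
    xi = np.asarray(xi, dtype=np.float64)
    xj = np.asarray(xj, dtype=np.float64)
    gamma = spec.gamma if spec.gamma is not None else 1.0 / xi.shape[0]
    if spec.kind == "linear":
        return float(xi @ xj)
    if spec.kind == "rbf":
        d = xi - xj
        return float(np.exp(-gamma * (d @ d)))
    return float((gamma * (xi @ xj) + spec.coef) ** spec.degree)


@dataclass
class SvmModel:
    """Kernel SVM with an attached Platt-style score calibration.

    Decision value d(x) = sum_i a_i y_i K(x, x_i) + b with a_i >= 0; the
    calibrated attack probability is sigmoid(A*d + B) fitted on training
    decision values.
    """

    svc: SVC
    spec: KernelSpec
    platt_a: float = 0.0
    platt_b: float = 0.0
    calibrated: bool = False

    def decision_value(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=np.float64))
        return self.svc.decision_function(x)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Labels: 1 = attack, 0 = bona fide (sign of the decision value)."""
        return (self.decision_value(features) >= 0).astype(int)

    @property
    def dual_coef(self) -> np.ndarray:
        """a_i * y_i for each support vector."""
        return self.svc.dual_coef_.ravel()

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def bias(self) -> float:
        return float(self.svc.intercept_[0])


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    spec: KernelSpec | None = None,
    C: float = 1.0,
) -> SvmModel:
    """Soft-margin kernel SVM; positive class = attack (label 1)."""
    if spec is None:
        spec = KernelSpec()
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise TrainingError("SVM training requires both classes")
    # variance-scaled default: on PCA-projected features the per-dimension
    # variances are the PCA eigenvalues (>> 1), so a bare 1/dim makes the
    # RBF kernel vanish away from the support vectors and memorize
    gamma = spec.gamma if spec.gamma is not None else "scale"
    kind = {"linear": "linear", "rbf": "rbf", "polynomial": "poly"}[spec.kind]
    svc = SVC(
        C=C, kernel=kind, gamma=gamma, coef0=spec.coef, degree=spec.degree,
    )
    svc.fit(x, y)
    return SvmModel(svc=svc, spec=spec)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def calibrate(model: SvmModel, features: np.ndarray, labels: np.ndarray) -> SvmModel:
    """Fit the logistic mapping decision value -> attack probability."""
    d = model.decision_value(features)
    y = np.asarray(labels, dtype=np.float64)
    if np.ptp(d) < 1e-12:
        raise TrainingError("degenerate decision values; cannot calibrate")

    def nll(ab: np.ndarray) -> float:
        p = _sigmoid(ab[0] * d + ab[1])
        eps = 1e-12
        return -float(np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    res = minimize(nll, x0=np.array([1.0, 0.0]), method="Nelder-Mead")
    model.platt_a, model.platt_b = float(res.x[0]), float(res.x[1])
    model.calibrated = True
    return model


def score(model: SvmModel, f: np.ndarray) -> np.ndarray:
    """Calibrated PAD score(s) in [0, 1]; higher = more attack-like."""
    if not model.calibrated:
        raise TrainingError("model is not calibrated; call calibrate() first")
    d = model.decision_value(f)
    return _sigmoid(model.platt_a * d + model.platt_b)


@dataclass(frozen=True)
class FusionWeights:
    w1: float
    w2: float

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0 or abs(self.w1 + self.w2 - 1.0) > 1e-12:
            raise ValidationError("weights must be non-negative and sum to 1")


def fuse(s1, s2, w: FusionWeights):
    """Weighted-sum score fusion S = w1*S1 + w2*S2 (convex combination)."""
    return w.w1 * np.asarray(s1) + w.w2 * np.asarray(s2)


def select_weights(
    s1_train: np.ndarray, s2_train: np.ndarray, labels: np.ndarray
) -> FusionWeights:
    """Grid-search w1 in {0, 0.01, ..., 1} for best training accuracy.

    Accuracy is evaluated at the 0.5 score threshold (score >= threshold
    classifies as attack).  Ties break toward w1 = 0.5, then toward the
    smaller w1.
    """
    s1 = np.asarray(s1_train, dtype=np.float64)
    s2 = np.asarray(s2_train, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    best: tuple[float, float, float] | None = None  # (-acc, |w1-0.5|, w1)
    for i in range(101):
        w1 = i / 100.0
        s = w1 * s1 + (1 - w1) * s2
        acc = float(np.mean((s >= 0.5).astype(int) == y))
        key = (-acc, abs(w1 - 0.5), w1)
        if best is None or key < best:
            best = key
    assert best is not None
    w1 = best[2]
    return FusionWeights(w1=w1, w2=round(1 - w1, 10))
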