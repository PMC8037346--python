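"""Uniform train/predict contract over the five classifier families.

Families: nu-SVM, C-SVM, linear SVM (liblinear-style), KNN and MLP.
Margin/weight optimisation is delegated to scikit-learn backends; this
module owns the configuration vocabulary (kernels and their parameters),
decoding, validation and the determinism contract.

Kernels (on pixel spectra x, y):

* RBF        K(x, y) = exp(-gamma ||x - y||^2)
* sigmoid    K(x, y) = tanh(gamma x.y + c0)
* polynomial K(x, y) = (gamma x.y + c0)^d
* linear     K(x, y) = x.y

The nu-SVM replaces the unbounded regulariser C with nu in (0, 1], an
upper bound on the training-error fraction and a lower bound on the
support-vector fraction, which makes it well suited to bounded-range
evolutionary encodings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC, NuSVC

import warnings

from .hsi_data import PixelSet

KERNEL_KINDS = ("rbf", "polynomial", "sigmoid", "linear")


@dataclass(frozen=True)
class KernelSpec:
    kind: str
    gamma: float | None = None
    coef0: float | None = None
    degree: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        need = {"rbf": ("gamma",), "sigmoid": ("gamma", "coef0"),
                "polynomial": ("gamma", "coef0", "degree"), "linear": ()}[self.kind]
        for name in need:
            if getattr(self, name) is None:
                raise ValueError(f"{self.kind} kernel requires parameter {name}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.degree is not None and (self.degree < 1 or int(self.degree) != self.degree):
            raise ValueError("degree must be an integer >= 1")


def kernel_eval(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> float:
    """Evaluate the kernel's closed form on a pair of spectra."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if spec.kind == "rbf":
        return float(np.exp(-spec.gamma * np.sum((x - y) ** 2)))
    if spec.kind == "sigmoid":
        return float(np.tanh(spec.gamma * x @ y + spec.coef0))
    if spec.kind == "polynomial":
        return float((spec.gamma * x @ y + spec.coef0) ** spec.degree)
    return float(x @ y)


@dataclass(frozen=True)
class SVMConfig:
    """nu-SVM, C-SVM or linear (liblinear) SVM specification."""

    variant: str  # {"nu", "c", "linear_c"}
    kernel: KernelSpec | None = None
    nu: float | None = None
    C: float | None = None
    loss: str = "hinge"  # linear_c only

    def __post_init__(self) -> None:
        if self.variant == "nu":
            if self.nu is None or not (0 < self.nu <= 1):
                raise ValueError("nu must lie in (0, 1]")
            if self.kernel is None:
                raise ValueError("nu-SVM requires a kernel")
        elif self.variant == "c":
            if self.C is None or self.C <= 0:
                raise ValueError("C must be > 0")
            if self.kernel is None:
                raise ValueError("C-SVM requires a kernel")
        elif self.variant == "linear_c":
            if self.C is None or self.C <= 0:
                raise ValueError("C must be > 0")
            if self.loss not in ("hinge", "squared"):
                raise ValueError("loss must be 'hinge' or 'squared'")
        else:
            raise ValueError(f"unknown SVM variant {self.variant!r}")


@dataclass(frozen=True)
class KNNConfig:
    n_neighbors: int = 5
    metric: str = "euclidean"
    weights: str = "distance"

    def __post_init__(self) -> None:
        if not 1 <= self.n_neighbors <= 20:
            raise ValueError("n_neighbors must be in [1, 20]")
        if self.metric not in ("euclidean", "manhattan", "chebyshev"):
            raise ValueError(f"unsupported metric {self.metric!r}")
        if self.weights not in ("uniform", "distance"):
            raise ValueError(f"unsupported weights {self.weights!r}")


@dataclass(frozen=True)
class MLPConfig:
    """SGD-trained multilayer perceptron (Glorot init, ReLU).

    The backend does not implement dropout; only ``dropout=0`` is
    accepted.
    """

    hidden_layers: tuple[int, ...] = (1000,)
    dropout: float = 0.0
    learning_rate: float = 0.001
    batch_size: int = 50
    iterations: int = 200

    def __post_init__(self) -> None:
        if not self.hidden_layers:
            raise ValueError("need at least one hidden layer")
        if self.dropout != 0.0:
            raise ValueError("dropout is not supported by the MLP backend; use 0")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.iterations < 1:
            raise ValueError("invalid MLP training parameters")


ClassifierConfig = SVMConfig | KNNConfig | MLPConfig


def _sk_kernel_args(kernel: KernelSpec) -> dict:
    m = {"rbf": "rbf", "sigmoid": "sigmoid", "polynomial": "poly", "linear": "linear"}
    args: dict = {"kernel": m[kernel.kind]}
    if kernel.gamma is not None:
        args["gamma"] = kernel.gamma
    if kernel.coef0 is not None:
        args["coef0"] = kernel.coef0
    if kernel.degree is not None:
        args["degree"] = kernel.degree
    return args


def _build_estimator(config: ClassifierConfig, seed: int):
    if isinstance(config, SVMConfig):
        if config.variant == "nu":
            return NuSVC(nu=config.nu, **_sk_kernel_args(config.kernel),
                         random_state=seed)
        if config.variant == "c":
            return SVC(C=config.C, **_sk_kernel_args(config.kernel), random_state=seed)
        loss = "hinge" if config.loss == "hinge" else "squared_hinge"
        return LinearSVC(C=config.C, loss=loss, random_state=seed)
    if isinstance(config, KNNConfig):
        return KNeighborsClassifier(
            n_neighbors=config.n_neighbors, metric=config.metric, weights=config.weights
        )
    if isinstance(config, MLPConfig):
        return MLPClassifier(
            hidden_layer_sizes=config.hidden_layers,
            activation="relu",
            solver="sgd",
            learning_rate_init=config.learning_rate,
            batch_size=config.batch_size,
            max_iter=config.iterations,
            random_state=seed,
        )
    raise TypeError(f"unsupported config type {type(config).__name__}")


@dataclass
class FittedModel:
    """A trained classifier bound to its config, seed and input width."""

    config: ClassifierConfig
    estimator: object
    n_features: int
    classes: np.ndarray = field(default_factory=lambda: np.array([]))


def train(config: ClassifierConfig, data: PixelSet, seed: int = 0) -> FittedModel:
    """Fit a classifier; deterministic given (config, data, seed)."""
    classes = np.unique(data.labels)
    if classes.size < 2:
        raise ValueError("training set must contain at least 2 classes")
    if data.n_features < 1:
        raise ValueError("training set has no features")
    est = _build_estimator(config, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(data.spectra, data.labels)
    return FittedModel(config, est, data.n_features, classes)


def predict(model: FittedModel, pixels: PixelSet) -> np.ndarray:
    """Predict one label per row; rejects a feature-width mismatch."""
    if pixels.n_features != model.n_features:
        raise ValueError(
            f"model was trained on {model.n_features} features, got {pixels.n_features}"
        )
    if len(pixels) == 0:
        return np.array([], dtype=np.int64)
    return np.asarray(model.estimator.predict(pixels.spectra), dtype=np.int64)
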