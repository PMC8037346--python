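"""Exhaustive grid-search baselines for model selection.

Shares the fitness implementation with the genetic optimiser
(:func:`hsi_evoselect.model_selection.evaluate_config`) but never
selects bands: the grid-search reference always uses the full feature
vector. Continuous parameter ranges are discretised with logarithmic
grids by default (7 points over a decade-spanning range) and linear
grids for small bounded ranges; every grid is user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .classifiers import (ClassifierConfig, KernelSpec, KNNConfig, MLPConfig,
                          SVMConfig)
from .hsi_data import PixelSet
from .model_selection import CVScheme, evaluate_config


def log_grid(lo: float, hi: float, n: int = 7) -> list[float]:
    return [float(x) for x in np.geomspace(lo, hi, n)]


def lin_grid(lo: float, hi: float, n: int = 7) -> list[float]:
    return [float(x) for x in np.linspace(lo, hi, n)]


@dataclass(frozen=True)
class ParamGrid:
    """Per-parameter value lists for one classifier family.

    ``family`` in {"svm", "nu_svm", "linear_svm", "knn", "mlp"}.
    Kernel-conditional parameters (gamma, c0, d) are only expanded where
    the kernel uses them.
    """

    family: str
    values: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("svm", "nu_svm", "linear_svm", "knn", "mlp"):
            raise ValueError(f"unknown classifier family {self.family!r}")


def default_grid(family: str) -> ParamGrid:
    """Default discretisation of the standard search ranges."""
    if family == "svm":
        return ParamGrid("svm", {
            "kernel": ["rbf", "polynomial", "sigmoid"],
            "C": log_grid(0.001, 1000),
            "gamma": log_grid(0.001, 5),
            "coef0": log_grid(0.01, 10),
            "degree": [1, 2, 3, 4, 5],
        })
    if family == "nu_svm":
        return ParamGrid("nu_svm", {
            "kernel": ["rbf", "polynomial", "sigmoid"],
            "nu": lin_grid(0.001, 0.4),
            "gamma": log_grid(0.001, 5),
            "coef0": log_grid(0.01, 10),
            "degree": [1, 2, 3, 4, 5],
        })
    if family == "linear_svm":
        return ParamGrid("linear_svm", {
            "loss": ["hinge", "squared"],
            "C": log_grid(0.001, 1000),
        })
    if family == "knn":
        return ParamGrid("knn", {
            "metric": ["euclidean", "manhattan", "chebyshev"],
            "weights": ["uniform", "distance"],
            "n_neighbors": list(range(1, 21)),
        })
    if family == "mlp":
        return ParamGrid("mlp", {
            "hidden_layers": [(1000,), (30, 30), (1000, 1000), (1000, 1000, 1000)],
            "learning_rate": [0.1, 0.01, 0.001],
            "batch_size": [50, 100],
            "iterations": list(range(50, 501, 50)),
        })
    raise ValueError(f"unknown classifier family {family!r}")


def _kernel_param_names(kind: str) -> tuple[str, ...]:
    return {"rbf": ("gamma",), "sigmoid": ("gamma", "coef0"),
            "polynomial": ("gamma", "coef0", "degree")}[kind]


def enumerate_grid(grid: ParamGrid) -> list[ClassifierConfig]:
    """Cartesian product of the grid, in deterministic order.

    For kernelised SVMs, only the parameters the kernel actually uses
    are expanded (an RBF grid never multiplies over degree or c0).
    """
    v = grid.values
    if not v or any(len(vals) == 0 for vals in v.values()):
        raise ValueError("empty grid")
    configs: list[ClassifierConfig] = []
    if grid.family in ("svm", "nu_svm"):
        reg_name = "C" if grid.family == "svm" else "nu"
        for kind in v["kernel"]:
            names = _kernel_param_names(kind)
            for reg in v[reg_name]:
                for combo in product(*(v[n] for n in names)):
                    kw = dict(zip(names, combo))
                    spec = KernelSpec(kind, **kw)
                    if grid.family == "svm":
                        configs.append(SVMConfig(variant="c", kernel=spec, C=reg))
                    else:
                        configs.append(SVMConfig(variant="nu", kernel=spec, nu=reg))
    elif grid.family == "linear_svm":
        for loss, C in product(v["loss"], v["C"]):
            configs.append(SVMConfig(variant="linear_c", C=C, loss=loss))
    elif grid.family == "knn":
        for metric, weights, k in product(v["metric"], v["weights"], v["n_neighbors"]):
            configs.append(KNNConfig(n_neighbors=k, metric=metric, weights=weights))
    else:  # mlp
        for hl, lr, bs, it in product(v["hidden_layers"], v["learning_rate"],
                                      v["batch_size"], v["iterations"]):
            configs.append(MLPConfig(hidden_layers=tuple(hl), learning_rate=lr,
                                     batch_size=bs, iterations=it))
    return configs


@dataclass
class GridSearchResult:
    best_config: ClassifierConfig
    best_fitness: float
    scores: list[tuple[ClassifierConfig, float]]


def grid_search(
    grid: ParamGrid,
    train: PixelSet,
    scheme: CVScheme,
    seed: int = 0,
) -> GridSearchResult:
    """Evaluate every grid point with the shared fitness; argmax wins.

    Ties are broken by enumeration order; a grid point whose training
    fails scores 0% and stays in the score table.
    """
    scheme.assign(train)
    scores: list[tuple[ClassifierConfig, float]] = []
    best_i, best_s = 0, -1.0
    for i, config in enumerate(enumerate_grid(grid)):
        s = evaluate_config(config, train, scheme, band_mask=None, seed=seed)
        scores.append((config, s))
        if s > best_s:
            best_i, best_s = i, s
    return GridSearchResult(scores[best_i][0], best_s, scores)
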