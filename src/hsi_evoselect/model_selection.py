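"""Cross-validation schemes and the shared fitness contract.

Both the genetic optimiser and the grid-search baseline score a
candidate configuration with :func:`evaluate_config`, so their fitness
values are directly comparable. Three fold schemes are supported:

* ``kfold_standard`` — stratified k-fold; train on k-1 folds, test on
  the held-out fold (the transductive setting).
* ``inverted_small_train`` — k folds; each iteration trains on a single
  fold further subsampled to a few examples per class and tests on the
  remaining folds (stress-tests generalisation from tiny samples).
* ``validation_anchored`` — k folds; each iteration trains on k-1 folds
  and scores on a fixed external validation set; the held-out fold is
  unused.

Fold assignments are drawn once per scheme instance, so fitness is a
static function of the configuration during an optimisation run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classifiers
from .hsi_data import PixelSet

CV_KINDS = ("kfold_standard", "inverted_small_train", "validation_anchored")


def accuracy(pred: np.ndarray, truth: np.ndarray, folds: np.ndarray | None = None) -> float:
    """Mean per-fold fraction of correctly labelled examples, in percent.

    With ``folds=None`` (or a single fold) this reduces to the plain
    fraction correct x 100. For multiclass data the per-fold score is
    micro accuracy, the natural reading of a TP/TN ratio when classes
    are balanced.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    if folds is None:
        folds = np.zeros(pred.shape, dtype=int)
    folds = np.asarray(folds)
    if folds.shape != pred.shape:
        raise ValueError("fold assignment length differs from predictions")
    scores = []
    for f in np.unique(folds):
        m = folds == f
        if not m.any():
            raise ValueError(f"fold {f} is empty")
        scores.append(np.mean(pred[m] == truth[m]))
    return float(np.mean(scores) * 100.0)


def stratified_fold_assignment(labels: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Per-row fold ids in [0, n_folds), stratified by class."""
    labels = np.asarray(labels)
    folds = np.empty(labels.shape[0], dtype=np.int64)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


@dataclass
class CVScheme:
    """A concrete fold scheme with frozen fold assignment.

    Build with :meth:`CVScheme.assign` once the training labels are
    known; ``validation`` is required for the anchored kind.
    """

    kind: str
    n_folds: int = 10
    per_class_subsample: int = 10
    validation: PixelSet | None = None
    seed: int = 0
    folds_: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in CV_KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.per_class_subsample < 1:
            raise ValueError("per_class_subsample must be >= 1")
        if self.kind == "validation_anchored" and self.validation is None:
            raise ValueError("validation_anchored scheme requires a validation set")

    def assign(self, train: PixelSet) -> "CVScheme":
        """Freeze the stratified fold assignment for ``train``."""
        rng = np.random.default_rng(self.seed)
        self.folds_ = stratified_fold_assignment(train.labels, self.n_folds, rng)
        return self

    def iter_splits(self, train: PixelSet):
        """Yield (fit_index_array, eval_pixelset) per CV iteration."""
        if self.folds_ is None or self.folds_.shape[0] != len(train):
            self.assign(train)
        rng = np.random.default_rng(self.seed + 1)
        for f in range(self.n_folds):
            held = self.folds_ == f
            if self.kind == "kfold_standard":
                yield np.flatnonzero(~held), train.take(np.flatnonzero(held))
            elif self.kind == "inverted_small_train":
                fit_idx = np.flatnonzero(held)
                sub = []
                lab = train.labels[fit_idx]
                for c in np.unique(lab):
                    cand = fit_idx[lab == c]
                    take = min(self.per_class_subsample, cand.size)
                    sub.append(rng.choice(cand, size=take, replace=False))
                yield np.concatenate(sub), train.take(np.flatnonzero(~held))
            else:  # validation_anchored
                yield np.flatnonzero(~held), self.validation


def evaluate_config(
    config: "classifiers.ClassifierConfig",
    train: PixelSet,
    scheme: CVScheme,
    band_mask: np.ndarray | None = None,
    seed: int = 0,
) -> float:
    """Cross-validated accuracy (%) of a configuration.

    This is the single fitness function shared by the GA and the grid
    search. ``band_mask`` restricts the feature columns (GA band
    selection); grid search always passes ``None``. A configuration
    whose fit fails (e.g. an infeasible nu) scores 0%.
    """
    if band_mask is not None:
        band_mask = np.asarray(band_mask, dtype=bool)
        if band_mask.shape != (train.n_features,):
            raise ValueError("band mask length does not match feature count")
        if not band_mask.any():
            return 0.0
    scores = []
    for fit_idx, eval_set in scheme.iter_splits(train):
        fit = train.take(fit_idx)
        ev = eval_set
        if band_mask is not None:
            fit = fit.with_spectra(fit.spectra[:, band_mask])
            ev = ev.with_spectra(ev.spectra[:, band_mask])
        try:
            model = classifiers.train(config, fit, seed=seed)
            pred = classifiers.predict(model, ev)
        except (ValueError, ArithmeticError):
            scores.append(0.0)
            continue
        scores.append(np.mean(pred == ev.labels) * 100.0)
    return float(np.mean(scores))
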