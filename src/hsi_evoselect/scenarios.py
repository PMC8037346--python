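"""Evaluation scenarios: transductive and inductive splits.

Three scenarios are supported, differing in where training, model
selection and test pixels come from:

* HTC (hyperspectral transductive classification): train and test
  pixels are sampled uniformly from the same images — the "closed
  world" setting. Model selection uses standard stratified 10-fold CV
  on the training set.
* HIC (hyperspectral inductive classification): train on frame scenes,
  test on comparison scenes. Model selection uses an inverted 10-fold
  scheme: each iteration trains on one fold (further subsampled to 10
  examples per class) and tests on the remaining nine.
* HICVS: HIC with a validation set sampled from the comparison-scene
  distribution (80/20 test/validation split, stratified by class and
  day). Model selection trains on nine folds and scores on the
  validation set; the final model is evaluated on the test set only.

The final model is always retrained on the entire training set and the
train/test evaluation is repeated several times; accuracy is reported
per acquisition day and combined, as mean +/- std over the repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classifiers, features, ga_optimiser, preprocessing
from .grid_search import ParamGrid, default_grid
from .grid_search import grid_search as _run_grid_search
from .hsi_data import HyperCube, LabelMap, PixelSet, concat_pixel_sets, flatten_annotated
from .model_selection import CVScheme, accuracy, stratified_fold_assignment  # noqa: F401 (re-export)

#: class dropped from the six-class problem (absent from some images)
DROPPED_CLASSES = frozenset({4})


@dataclass
class PipelineConfig:
    """Preprocessing + feature-extraction settings for a whole run."""

    median_radius: int = 1
    normalize: bool = True
    removed_ranges: tuple[tuple[int, int], ...] | None = preprocessing.DEFAULT_REMOVAL.ranges
    derivative: bool = True
    drop_classes: frozenset[int] = DROPPED_CLASSES
    border_mode: str = "reflect"


def prepare_image(cube: HyperCube, labels: LabelMap, config: PipelineConfig | None = None) -> PixelSet:
    """Run the full per-image chain: filter, normalise, remove bands,
    flatten annotated pixels, derivative features."""
    config = config or PipelineConfig()
    removal = (
        preprocessing.BandRemovalSpec(config.removed_ranges)
        if config.removed_ranges is not None
        else None
    )
    cube = preprocessing.preprocess_cube(
        cube,
        median_radius=config.median_radius,
        normalize=config.normalize,
        removal=removal,
        border_mode=config.border_mode,
    )
    pixels = flatten_annotated(cube, labels, config.drop_classes)
    return features.extract(pixels, enabled=config.derivative)


def prepare_dataset(
    dataset: list[tuple[HyperCube, LabelMap]], config: PipelineConfig | None = None
) -> list[PixelSet]:
    return [prepare_image(c, l, config) for c, l in dataset]


@dataclass
class ScenarioSplit:
    train: PixelSet
    test: PixelSet
    scheme: CVScheme
    validation: PixelSet | None = None


def _as_pixel_sets(dataset, config) -> list[PixelSet]:
    if dataset and isinstance(dataset[0], PixelSet):
        return list(dataset)
    return prepare_dataset(dataset, config)


def _sample_per_class(pixels: PixelSet, per_class: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform per-class sample indices; errors if a class is short."""
    picked = []
    for c in np.unique(pixels.labels):
        idx = np.flatnonzero(pixels.labels == c)
        if idx.size < per_class:
            raise ValueError(
                f"class {c} has only {idx.size} pixels, need {per_class}"
            )
        picked.append(rng.choice(idx, size=per_class, replace=False))
    return np.sort(np.concatenate(picked))


def build_htc(
    dataset,
    per_class: int | None = None,
    seed: int = 0,
    n_folds: int = 10,
    config: PipelineConfig | None = None,
) -> ScenarioSplit:
    """Transductive split: an equal per-class, per-image sample forms
    the training set; every other annotated pixel is test.

    ``per_class`` defaults to the size of the least numerous class over
    all images.
    """
    images = _as_pixel_sets(dataset, config)
    class_ids = np.unique(np.concatenate([p.labels for p in images]))
    for i, p in enumerate(images):
        missing = set(class_ids) - set(np.unique(p.labels))
        if missing:
            raise ValueError(f"image {i} is missing classes {sorted(missing)}")
    if per_class is None:
        per_class = min(
            int(np.min(np.bincount(p.labels)[np.unique(p.labels)])) for p in images
        )
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for p in images:
        idx = _sample_per_class(p, per_class, rng)
        rest = np.setdiff1d(np.arange(len(p)), idx)
        train_parts.append(p.take(idx))
        test_parts.append(p.take(rest))
    return ScenarioSplit(
        train=concat_pixel_sets(train_parts),
        test=concat_pixel_sets(test_parts),
        scheme=CVScheme("kfold_standard", n_folds=n_folds, seed=seed),
    )


def build_hic(
    frame_images,
    comparison_images,
    per_class: int = 250,
    seed: int = 0,
    n_folds: int = 10,
    per_class_subsample: int = 10,
    config: PipelineConfig | None = None,
) -> ScenarioSplit:
    """Inductive split: train sampled from frame scenes only; every
    annotated comparison pixel is test."""
    frames = _as_pixel_sets(frame_images, config)
    comps = _as_pixel_sets(comparison_images, config)
    rng = np.random.default_rng(seed)
    train_parts = [p.take(_sample_per_class(p, per_class, rng)) for p in frames]
    return ScenarioSplit(
        train=concat_pixel_sets(train_parts),
        test=concat_pixel_sets(comps),
        scheme=CVScheme(
            "inverted_small_train",
            n_folds=n_folds,
            per_class_subsample=per_class_subsample,
            seed=seed,
        ),
    )


def build_hicvs(
    frame_images,
    comparison_images,
    per_class: int = 250,
    test_frac: float = 0.8,
    seed: int = 0,
    n_folds: int = 10,
    config: PipelineConfig | None = None,
) -> ScenarioSplit:
    """HIC plus a validation set: comparison pixels are partitioned
    (stratified by class and day) into test and validation; model
    selection scores on the validation set, the final model is tested
    on the test partition only, and no comparison pixel is trained on."""
    frames = _as_pixel_sets(frame_images, config)
    comps = _as_pixel_sets(comparison_images, config)
    rng = np.random.default_rng(seed)
    train_parts = [p.take(_sample_per_class(p, per_class, rng)) for p in frames]
    comp_all = concat_pixel_sets(comps)
    # stratify by (class, day)
    strata = np.array(
        [f"{l}|{s[1]}" for l, s in zip(comp_all.labels, comp_all.source)]
    )
    test_mask = np.zeros(len(comp_all), dtype=bool)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        n_test = int(np.floor(test_frac * idx.size))
        test_mask[idx[:n_test]] = True
    validation = comp_all.take(np.flatnonzero(~test_mask))
    test = comp_all.take(np.flatnonzero(test_mask))
    return ScenarioSplit(
        train=concat_pixel_sets(train_parts),
        test=test,
        validation=validation,
        scheme=CVScheme(
            "validation_anchored", n_folds=n_folds, validation=validation, seed=seed
        ),
    )


@dataclass
class EvalReport:
    """Per-day and combined accuracy, mean +/- std over repeats."""

    per_day: dict[str, tuple[float, float]]
    combined: tuple[float, float]
    best_config: object
    fitness: float
    selected_bands: int | None = None
    n_features: int | None = None
    trace: ga_optimiser.GATrace | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "per_day": {k: {"mean": m, "std": s} for k, (m, s) in self.per_day.items()},
            "combined": {"mean": self.combined[0], "std": self.combined[1]},
            "fitness": self.fitness,
            "selected_bands": self.selected_bands,
            "n_features": self.n_features,
            "best_config": repr(self.best_config),
        }


def run_experiment(
    split: ScenarioSplit,
    optimiser: str = "ga",
    ga_params: ga_optimiser.GAParams | None = None,
    grid: ParamGrid | None = None,
    repeats: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Optimise on the split, retrain the winner on the full training
    set, and evaluate per-day and combined test accuracy over
    ``repeats`` seeded repetitions.

    ``optimiser`` is "ga" (genetic model + band selection) or "gs"
    (grid search, full feature vector). Repeats redraw the classifier's
    internal randomness; the split itself is fixed by construction.
    """
    mask: np.ndarray | None = None
    trace = None
    if optimiser == "ga":
        params = ga_params or ga_optimiser.GAParams()
        if params.seed == 0:
            params.seed = seed
        trace = ga_optimiser.evolve(split.train, split.scheme, params)
        best_config = trace.best.decode()
        mask = trace.best.band_mask()
        fitness = trace.final_fitness
        selected = trace.selected_bands
    elif optimiser == "gs":
        g = grid or default_grid("nu_svm")
        res = _run_grid_search(g, split.train, split.scheme, seed=seed)
        best_config, fitness, selected = res.best_config, res.best_fitness, None
    else:
        raise ValueError("optimiser must be 'ga' or 'gs'")

    train = split.train
    test = split.test
    if mask is not None:
        train = train.with_spectra(train.spectra[:, mask])
        test = test.with_spectra(test.spectra[:, mask])

    day_keys = test.day_keys()
    per_day_runs: dict[str, list[float]] = {k: [] for k in day_keys}
    combined_runs: list[float] = []
    test_keys = np.array([f"{s}({d})" for s, d in test.source])
    for r in range(max(1, repeats)):
        rep_seed = seed + 1000 * (r + 1)
        order = np.random.default_rng(rep_seed).permutation(len(train))
        model = classifiers.train(best_config, train.take(order), seed=rep_seed)
        pred = classifiers.predict(model, test)
        combined_runs.append(float(np.mean(pred == test.labels) * 100.0))
        for k in day_keys:
            m = test_keys == k
            per_day_runs[k].append(float(np.mean(pred[m] == test.labels[m]) * 100.0))

    def agg(xs: list[float]) -> tuple[float, float]:
        return float(np.mean(xs)), float(np.std(xs))

    return EvalReport(
        per_day={k: agg(v) for k, v in per_day_runs.items()},
        combined=agg(combined_runs),
        best_config=best_config,
        fitness=fitness,
        selected_bands=selected,
        n_features=split.train.n_features,
        trace=trace,
    )
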