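"""Genetic optimisation of nu-SVM parameters with per-band selection.

A chromosome couples five model genes — kernel kind, regulariser nu,
polynomial degree d, kernel width gamma and kernel offset c0 — with one
selection bit per feature band, so model selection and band selection
happen in a single evolutionary search. The generational loop uses
tournament selection (size 3, with replacement), crossover and mutation
each applied with probability 0.8, and a one-individual elitist
carryover, so the best fitness found never decreases.

Default gene ranges: kernel in {rbf, polynomial, sigmoid},
nu in [0.001, 0.4], d in {1..5}, gamma in [0.001, 5], c0 in [0.01, 10].
The band-gene count equals the feature count of the training data
(113 on preprocessed spectra, 112 after derivative extraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classifiers import KernelSpec, SVMConfig
from .hsi_data import PixelSet
from .model_selection import CVScheme, evaluate_config

GA_KERNELS = ("rbf", "polynomial", "sigmoid")
N_MODEL_GENES = 5


@dataclass(frozen=True)
class GeneRanges:
    """Admissible values for the five model genes.

    Degenerate ranges (lo == hi, or a single kernel) are allowed; they
    freeze a gene, which is how small discrete search spaces are built
    for validation against exhaustive enumeration.
    """

    kernels: tuple[str, ...] = GA_KERNELS
    nu: tuple[float, float] = (0.001, 0.4)
    degree: tuple[int, int] = (1, 5)
    gamma: tuple[float, float] = (0.001, 5.0)
    coef0: tuple[float, float] = (0.01, 10.0)

    def __post_init__(self) -> None:
        if not self.kernels or any(k not in GA_KERNELS for k in self.kernels):
            raise ValueError(f"kernels must be a non-empty subset of {GA_KERNELS}")
        for name in ("nu", "degree", "gamma", "coef0"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"range for {name} is inverted")


DEFAULT_RANGES = GeneRanges()


@dataclass(frozen=True)
class Chromosome:
    """5 model genes + one selection bit per feature band."""

    kernel: str
    nu: float
    degree: int
    gamma: float
    coef0: float
    bands: tuple[int, ...]  # 0/1 per band

    @property
    def n_genes(self) -> int:
        return N_MODEL_GENES + len(self.bands)

    @property
    def n_selected(self) -> int:
        return int(sum(self.bands))

    def band_mask(self) -> np.ndarray:
        return np.asarray(self.bands, dtype=bool)

    def genes(self) -> tuple:
        """Flat gene tuple (model genes first, then band bits)."""
        return (self.kernel, self.nu, self.degree, self.gamma, self.coef0, *self.bands)

    def validate(self, ranges: GeneRanges = DEFAULT_RANGES) -> None:
        if self.kernel not in ranges.kernels:
            raise ValueError(f"kernel {self.kernel!r} outside admissible set")
        for name in ("nu", "degree", "gamma", "coef0"):
            lo, hi = getattr(ranges, name)
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"gene {name}={v} outside [{lo}, {hi}]")
        if any(b not in (0, 1) for b in self.bands):
            raise ValueError("band genes must be 0/1")

    def decode(self) -> SVMConfig:
        """Decode to a trainable nu-SVM config.

        Genes irrelevant to the chosen kernel (e.g. d under RBF) are
        carried silently and ignored here, keeping the chromosome
        fixed-length.
        """
        if self.kernel == "rbf":
            k = KernelSpec("rbf", gamma=self.gamma)
        elif self.kernel == "sigmoid":
            k = KernelSpec("sigmoid", gamma=self.gamma, coef0=self.coef0)
        else:
            k = KernelSpec("polynomial", gamma=self.gamma, coef0=self.coef0,
                           degree=int(self.degree))
        return SVMConfig(variant="nu", kernel=k, nu=self.nu)


def _from_genes(genes: tuple) -> Chromosome:
    return Chromosome(genes[0], genes[1], genes[2], genes[3], genes[4],
                      tuple(genes[N_MODEL_GENES:]))


@dataclass
class GAParams:
    """Evolutionary loop settings (field names mirror the usual table
    of GA hyperparameters: population, epochs, tournament size, operator
    probabilities, elitism)."""

    population_size: int = 200
    epochs: int = 100
    tournament_size: int = 3
    crossover_prob: float = 0.8
    mutation_prob: float = 0.8
    elite_count: int = 1
    crossover_method: str = "uniform"  # or "one_point"
    ranges: GeneRanges = field(default_factory=GeneRanges)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.epochs < 0 or self.tournament_size < 1:
            raise ValueError("population, epochs and tournament size must be positive")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0 <= p <= 1:
                raise ValueError("operator probabilities must lie in [0, 1]")
        if self.elite_count < 0 or self.elite_count > self.population_size:
            raise ValueError("elite_count out of range")
        if self.crossover_method not in ("uniform", "one_point"):
            raise ValueError("crossover_method must be 'uniform' or 'one_point'")


@dataclass
class GATrace:
    """Per-generation statistics plus the winning chromosome."""

    best_fitness: list[float]
    mean_fitness: list[float]
    best: Chromosome
    n_evaluations: int = 0

    @property
    def final_fitness(self) -> float:
        return self.best_fitness[-1]

    @property
    def selected_bands(self) -> int:
        return self.best.n_selected

    def to_rows(self) -> list[dict]:
        return [
            {"generation": g, "best": b, "mean": m, "selected_bands": self.best.n_selected}
            for g, (b, m) in enumerate(zip(self.best_fitness, self.mean_fitness))
        ]


def random_chromosome(
    n_features: int, rng: np.random.Generator, ranges: GeneRanges = DEFAULT_RANGES
) -> Chromosome:
    """Model genes uniform over their ranges; band bits are fair coins."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return Chromosome(
        kernel=ranges.kernels[rng.integers(len(ranges.kernels))],
        nu=float(rng.uniform(*ranges.nu)),
        degree=int(rng.integers(ranges.degree[0], ranges.degree[1] + 1)),
        gamma=float(rng.uniform(*ranges.gamma)),
        coef0=float(rng.uniform(*ranges.coef0)),
        bands=tuple(int(b) for b in rng.integers(0, 2, size=n_features)),
    )


def _mutable_model_genes(ranges: GeneRanges) -> list[int]:
    out = []
    if len(ranges.kernels) > 1:
        out.append(0)
    if ranges.nu[0] < ranges.nu[1]:
        out.append(1)
    if ranges.degree[0] < ranges.degree[1]:
        out.append(2)
    if ranges.gamma[0] < ranges.gamma[1]:
        out.append(3)
    if ranges.coef0[0] < ranges.coef0[1]:
        out.append(4)
    return out


def mutate(
    c: Chromosome, rng: np.random.Generator, ranges: GeneRanges = DEFAULT_RANGES
) -> Chromosome:
    """Modify exactly one gene; the input chromosome is untouched.

    A band gene is flipped to its opposite value; a model gene is
    redrawn from its admissible range, excluding its current value for
    the discrete kernel/degree genes so the mutation is never a no-op.
    Genes with a degenerate (single-value) range are never drawn.
    """
    positions = _mutable_model_genes(ranges) + list(
        range(N_MODEL_GENES, N_MODEL_GENES + len(c.bands))
    )
    if not positions:
        return c
    pos = positions[rng.integers(len(positions))]
    if pos >= N_MODEL_GENES:
        i = pos - N_MODEL_GENES
        bands = list(c.bands)
        bands[i] = 1 - bands[i]
        return replace(c, bands=tuple(bands))
    if pos == 0:
        others = [k for k in ranges.kernels if k != c.kernel]
        return replace(c, kernel=others[rng.integers(len(others))])
    if pos == 1:
        return replace(c, nu=float(rng.uniform(*ranges.nu)))
    if pos == 2:
        choices = [d for d in range(ranges.degree[0], ranges.degree[1] + 1) if d != c.degree]
        return replace(c, degree=int(choices[rng.integers(len(choices))]))
    if pos == 3:
        return replace(c, gamma=float(rng.uniform(*ranges.gamma)))
    return replace(c, coef0=float(rng.uniform(*ranges.coef0)))


def crossover(
    a: Chromosome,
    b: Chromosome,
    rng: np.random.Generator,
    method: str = "uniform",
) -> tuple[Chromosome, Chromosome]:
    """Recombine two chromosomes; per position, the children's gene pair
    is a permutation of the parents' pair.

    ``uniform``: every position independently swapped with probability
    0.5. ``one_point``: positions beyond a drawn cut index swapped.
    """
    ga, gb = list(a.genes()), list(b.genes())
    if len(ga) != len(gb):
        raise ValueError("chromosomes have different gene counts")
    n = len(ga)
    if method == "uniform":
        swap = rng.random(n) < 0.5
        for i in np.flatnonzero(swap):
            ga[i], gb[i] = gb[i], ga[i]
    elif method == "one_point":
        cut = int(rng.integers(n))
        ga[cut:], gb[cut:] = gb[cut:], ga[cut:]
    else:
        raise ValueError("method must be 'uniform' or 'one_point'")
    return _from_genes(tuple(ga)), _from_genes(tuple(gb))


def fitness(
    c: Chromosome,
    train: PixelSet,
    scheme: CVScheme,
    seed: int = 0,
) -> float:
    """Cross-validated accuracy (%) of the decoded nu-SVM restricted to
    the chromosome's selected bands. An all-zero band mask scores 0%."""
    if len(c.bands) != train.n_features:
        raise ValueError("band-gene count does not match feature count")
    if c.n_selected == 0:
        return 0.0
    return evaluate_config(c.decode(), train, scheme, band_mask=c.band_mask(), seed=seed)


def evolve(train: PixelSet, scheme: CVScheme, params: GAParams) -> GATrace:
    """Run the generational loop and return the full trace.

    Tournament selection with replacement (ties broken by the first
    encountered maximum), crossover w.p. ``crossover_prob`` per pair,
    mutation w.p. ``mutation_prob`` per individual (one gene modified),
    and elitist carryover of the single best individual. Fitness folds
    are frozen once per run, so fitness is a static function and the
    per-generation best is non-decreasing.
    """
    rng = np.random.default_rng(params.seed)
    scheme.assign(train)
    cache: dict[tuple, float] = {}
    n_evals = 0

    def fit_of(c: Chromosome) -> float:
        nonlocal n_evals
        key = c.genes()
        if key not in cache:
            cache[key] = fitness(c, train, scheme, seed=params.seed)
            n_evals += 1
        return cache[key]

    pop = [random_chromosome(train.n_features, rng, params.ranges)
           for _ in range(params.population_size)]
    scores = [fit_of(c) for c in pop]
    best_hist = [max(scores)]
    mean_hist = [float(np.mean(scores))]
    best_idx = int(np.argmax(scores))
    best, best_score = pop[best_idx], scores[best_idx]

    for _ in range(params.epochs):
        # tournament selection, with replacement
        parents = []
        for _ in range(params.population_size):
            contenders = rng.integers(len(pop), size=params.tournament_size)
            winner = contenders[int(np.argmax([scores[i] for i in contenders]))]
            parents.append(pop[winner])
        # crossover in adjacent pairs
        children: list[Chromosome] = []
        for i in range(0, len(parents) - 1, 2):
            a, b = parents[i], parents[i + 1]
            if rng.random() < params.crossover_prob:
                a, b = crossover(a, b, rng, params.crossover_method)
            children.extend((a, b))
        if len(parents) % 2:
            children.append(parents[-1])
        # mutation per individual
        children = [
            mutate(c, rng, params.ranges) if rng.random() < params.mutation_prob else c
            for c in children
        ]
        # elitist replacement of the first slots
        for e in range(params.elite_count):
            if e < len(children):
                children[e] = best
        pop = children
        scores = [fit_of(c) for c in pop]
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            best, best_score = pop[gen_best], scores[gen_best]
        best_hist.append(best_score)
        mean_hist.append(float(np.mean(scores)))

    return GATrace(best_hist, mean_hist, best, n_evaluations=n_evals)
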