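import numpy as np
import pytest

import hsi_evoselect as h
from hsi_evoselect.ga_optimiser import N_MODEL_GENES

#: degenerate ranges freezing every continuous gene -> tiny discrete space
FROZEN = h.GeneRanges(nu=(0.2, 0.2), degree=(2, 2), gamma=(0.5, 0.5),
                      coef0=(1.0, 1.0))


def _gene_diff(a: h.Chromosome, b: h.Chromosome) -> int:
    return sum(x != y for x, y in zip(a.genes(), b.genes()))


class TestRandomChromosome:
    def test_deterministic_under_seed(self):
        a = h.random_chromosome(20, np.random.default_rng(3))
        b = h.random_chromosome(20, np.random.default_rng(3))
        assert a == b

    def test_band_fraction_near_half(self):
        # binomial concentration: mean selected fraction over 10^4 draws
        rng = np.random.default_rng(0)
        frac = np.mean([h.random_chromosome(10, rng).n_selected / 10
                        for _ in range(10_000)])
        assert abs(frac - 0.5) < 0.02

    def test_genes_within_ranges(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            h.random_chromosome(8, rng).validate()

    def test_zero_features_rejected(self):
        with pytest.raises(ValueError):
            h.random_chromosome(0, np.random.default_rng(0))


class TestMutate:
    def test_exactly_one_gene_differs(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            c = h.random_chromosome(12, rng)
            m = h.mutate(c, rng)
            assert _gene_diff(c, m) == 1

    def test_band_gene_flipped_to_opposite(self):
        rng = np.random.default_rng(4)
        c = h.random_chromosome(6, rng)
        for _ in range(200):
            m = h.mutate(c, rng)
            if m.bands != c.bands:
                (i,) = [i for i in range(6) if m.bands[i] != c.bands[i]]
                assert m.bands[i] == 1 - c.bands[i]
                break
        else:
            pytest.fail("no band mutation observed in 200 draws")

    def test_redrawn_parameters_stay_in_bounds(self):
        rng = np.random.default_rng(5)
        c = h.random_chromosome(4, rng)
        for _ in range(1000):
            c = h.mutate(c, rng)
            c.validate()

    def test_original_untouched(self):
        rng = np.random.default_rng(6)
        c = h.random_chromosome(5, rng)
        before = c.genes()
        h.mutate(c, rng)
        assert c.genes() == before


class TestCrossover:
    @pytest.mark.parametrize("method", ["uniform", "one_point"])
    def test_identical_parents_give_identical_children(self, method, rng):
        c = h.random_chromosome(10, rng)
        k1, k2 = h.crossover(c, c, rng, method)
        assert k1 == c and k2 == c

    @pytest.mark.parametrize("method", ["uniform", "one_point"])
    def test_per_position_gene_conservation(self, method, rng):
        a = h.random_chromosome(15, rng)
        b = h.random_chromosome(15, rng)
        k1, k2 = h.crossover(a, b, rng, method)
        for x, y, p, q in zip(k1.genes(), k2.genes(), a.genes(), b.genes()):
            assert {x, y} == {p, q}

    def test_one_point_cut_at_zero_swaps_whole_parents(self):
        class Cut0:
            def integers(self, n):
                return 0
        a = h.random_chromosome(5, np.random.default_rng(7))
        b = h.random_chromosome(5, np.random.default_rng(8))
        k1, k2 = h.crossover(a, b, Cut0(), "one_point")
        assert k1 == b and k2 == a


class TestFitness:
    def test_all_bands_on_separable_data_is_100(self, toy_pixels):
        c = h.Chromosome("rbf", 0.1, 2, 0.5, 1.0,
                         tuple([1] * toy_pixels.n_features))
        scheme = h.CVScheme("kfold_standard", n_folds=5, seed=0)
        assert h.fitness(c, toy_pixels, scheme) == pytest.approx(100.0)

    def test_uninformative_bands_score_near_chance(self, banded_pixels):
        S, pix = banded_pixels
        complement = tuple(1 if i not in S else 0 for i in range(pix.n_features))
        c = h.Chromosome("rbf", 0.2, 2, 0.5, 1.0, complement)
        scheme = h.CVScheme("kfold_standard", n_folds=5, seed=0)
        score = h.fitness(c, pix, scheme)
        assert score < 60.0  # chance for 3 classes is ~33%

    def test_informative_bands_score_high(self, banded_pixels):
        S, pix = banded_pixels
        only_s = tuple(1 if i in S else 0 for i in range(pix.n_features))
        c = h.Chromosome("rbf", 0.2, 2, 0.5, 1.0, only_s)
        scheme = h.CVScheme("kfold_standard", n_folds=5, seed=0)
        assert h.fitness(c, pix, scheme) > 90.0

    def test_zero_band_mask_scores_zero(self, toy_pixels):
        c = h.Chromosome("rbf", 0.2, 2, 0.5, 1.0, (0,) * toy_pixels.n_features)
        scheme = h.CVScheme("kfold_standard", n_folds=5, seed=0)
        assert h.fitness(c, toy_pixels, scheme) == 0.0

    def test_deterministic(self, toy_pixels):
        rng = np.random.default_rng(9)
        c = h.random_chromosome(toy_pixels.n_features, rng)
        scheme = h.CVScheme("kfold_standard", n_folds=5, seed=3).assign(toy_pixels)
        assert h.fitness(c, toy_pixels, scheme) == h.fitness(c, toy_pixels, scheme)


class TestEvolve:
    def test_elitism_best_fitness_non_decreasing(self, toy_pixels):
        params = h.GAParams(population_size=10, epochs=8, seed=1)
        scheme = h.CVScheme("kfold_standard", n_folds=5, seed=1)
        trace = h.evolve(toy_pixels, scheme, params)
        assert all(b2 >= b1 for b1, b2 in
                   zip(trace.best_fitness, trace.best_fitness[1:]))
        assert len(trace.best_fitness) == params.epochs + 1

    def test_matches_exhaustive_enumeration_on_tiny_space(self, toy_pixels):
        # search space: 3 kernels x 4 band patterns over 2 engineered features
        pix = toy_pixels.with_spectra(toy_pixels.spectra[:, :2])
        scheme = h.CVScheme("kfold_standard", n_folds=5, seed=2)
        scheme.assign(pix)
        best_exhaustive = max(
            h.fitness(h.Chromosome(k, 0.2, 2, 0.5, 1.0, bands), pix, scheme)
            for k in ("rbf", "polynomial", "sigmoid")
            for bands in [(0, 0), (0, 1), (1, 0), (1, 1)]
        )
        params = h.GAParams(population_size=12, epochs=15, ranges=FROZEN, seed=2)
        trace = h.evolve(pix, scheme, params)
        assert trace.final_fitness == pytest.approx(best_exhaustive)

    def test_epoch_zero_returns_initial_population_only(self, toy_pixels):
        params = h.GAParams(population_size=5, epochs=0, seed=3)
        scheme = h.CVScheme("kfold_standard", n_folds=5, seed=3)
        trace = h.evolve(toy_pixels, scheme, params)
        assert len(trace.best_fitness) == 1

    def test_band_recovery_prefers_informative_bands(self, banded_pixels):
        S, pix = banded_pixels
        scheme = h.CVScheme("kfold_standard", n_folds=5, seed=4)
        params = h.GAParams(population_size=14, epochs=10, seed=4)
        trace = h.evolve(pix, scheme, params)
        mask = trace.best.band_mask()
        in_s = np.mean([mask[i] for i in S])
        out_s = np.mean([mask[i] for i in range(pix.n_features) if i not in S])
        assert in_s > out_s
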