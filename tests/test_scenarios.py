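import numpy as np
import pytest

import hsi_evoselect as h


class TestAccuracyMetric:
    def test_all_correct_is_100(self):
        p = np.array([1, 2, 3, 1])
        assert h.accuracy(p, p, np.array([0, 0, 1, 1])) == 100.0

    def test_all_wrong_is_0(self):
        assert h.accuracy(np.ones(4), np.full(4, 2)) == 0.0

    def test_two_fold_mean(self):
        # fold A: 3/4 correct, fold B: 1/4 correct -> (75 + 25) / 2 = 50
        truth = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        pred = np.array([1, 1, 1, 2, 2, 1, 1, 1])
        folds = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert h.accuracy(pred, truth, folds) == 50.0

    def test_single_fold_equals_fraction_correct(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(1, 4, size=50)
        pred = rng.integers(1, 4, size=50)
        assert h.accuracy(pred, truth) == pytest.approx(
            np.mean(pred == truth) * 100.0
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            h.accuracy(np.ones(3), np.ones(4))


class TestCVSchemes:
    def test_inverted_scheme_trains_on_small_single_fold(self, toy_pixels):
        scheme = h.CVScheme("inverted_small_train", n_folds=5,
                            per_class_subsample=4, seed=0)
        splits = list(scheme.iter_splits(toy_pixels))
        assert len(splits) == 5
        n_classes = np.unique(toy_pixels.labels).size
        for fit_idx, eval_set in splits:
            assert fit_idx.size == 4 * n_classes
            assert len(eval_set) == len(toy_pixels) - len(toy_pixels) // 5

    def test_anchored_scheme_scores_on_validation(self, toy_pixels):
        val = toy_pixels.take(np.arange(10))
        scheme = h.CVScheme("validation_anchored", n_folds=5, validation=val,
                            seed=0)
        for fit_idx, eval_set in scheme.iter_splits(toy_pixels):
            assert eval_set is val
            assert fit_idx.size == len(toy_pixels) - len(toy_pixels) // 5

    def test_anchored_requires_validation(self):
        with pytest.raises(ValueError, match="validation"):
            h.CVScheme("validation_anchored", n_folds=5)


class TestBuildHtc:
    def test_training_size_is_per_class_product(self, prepared_study):
        split = h.build_htc(prepared_study, per_class=30, seed=0)
        assert len(split.train) == 30 * 6 * 7
        assert split.scheme.kind == "kfold_standard"

    def test_train_and_test_disjoint_and_exhaustive(self, prepared_study):
        split = h.build_htc(prepared_study, per_class=30, seed=0)
        total = sum(len(p) for p in prepared_study)
        assert len(split.train) + len(split.test) == total

    def test_default_per_class_is_global_minimum(self, prepared_study):
        split = h.build_htc(prepared_study, seed=0)
        n_img, n_cls = len(prepared_study), 6
        min_count = min(int(np.min(np.bincount(p.labels)[np.unique(p.labels)]))
                        for p in prepared_study)
        assert len(split.train) == min_count * n_cls * n_img

    def test_missing_class_rejected(self, prepared_study):
        broken = list(prepared_study)
        p = broken[0]
        keep = p.labels != 7
        broken[0] = p.take(np.flatnonzero(keep))
        with pytest.raises(ValueError, match="missing classes"):
            h.build_htc(broken, per_class=10, seed=0)


class TestBuildHic:
    @pytest.fixture(scope="class")
    def frame_comp(self, prepared_study):
        frames = [p for p in prepared_study if p.source[0][0] == "F"]
        comps = [p for p in prepared_study if p.source[0][0] == "E"]
        return frames, comps

    def test_training_size(self, frame_comp):
        frames, comps = frame_comp
        split = h.build_hic(frames, comps, per_class=40, seed=0)
        assert len(split.train) == 40 * 6 * 4
        assert split.scheme.kind == "inverted_small_train"
        assert split.scheme.n_folds == 10
        assert split.scheme.per_class_subsample == 10

    def test_no_comparison_pixel_in_train(self, frame_comp):
        frames, comps = frame_comp
        split = h.build_hic(frames, comps, per_class=40, seed=0)
        assert all(s == "F" for s, _ in split.train.source)
        assert all(s == "E" for s, _ in split.test.source)
        assert len(split.test) == sum(len(p) for p in comps)

    def test_short_class_rejected(self, frame_comp):
        frames, comps = frame_comp
        with pytest.raises(ValueError, match="need"):
            h.build_hic(frames, comps, per_class=10**6, seed=0)


class TestBuildHicvs:
    @pytest.fixture(scope="class")
    def split(self, prepared_study):
        frames = [p for p in prepared_study if p.source[0][0] == "F"]
        comps = [p for p in prepared_study if p.source[0][0] == "E"]
        return h.build_hicvs(frames, comps, per_class=40, seed=0), comps

    def test_validation_and_test_partition_comparison(self, split):
        s, comps = split
        total = sum(len(p) for p in comps)
        assert len(s.test) + len(s.validation) == total

    def test_split_ratio_80_20_per_stratum(self, split):
        s, _ = split
        frac = len(s.validation) / (len(s.validation) + len(s.test))
        # floor rounding per (class, day) stratum allows one pixel each
        assert abs(frac - 0.20) < 0.01

    def test_no_comparison_pixel_in_train(self, split):
        s, _ = split
        assert all(sc == "F" for sc, _ in s.train.source)

    def test_scheme_anchored_to_validation(self, split):
        s, _ = split
        assert s.scheme.kind == "validation_anchored"
        assert s.scheme.validation is s.validation


class TestRunExperiment:
    @pytest.fixture(scope="class")
    def htc_split(self):
        # well-separated regime: inter-class mean gaps >> noise sigma
        spec = h.SceneSpec(height=40, width=40, pixels_per_class=150,
                           n_classes=6, noise_sigma=0.005)
        study = h.generate_study(spec, seed=21)
        return h.build_htc(study, per_class=30, seed=1, n_folds=5)

    def test_well_separated_htc_scores_high(self, htc_split):
        params = h.GAParams(population_size=10, epochs=6, seed=1)
        report = h.run_experiment(htc_split, "ga", ga_params=params,
                                  repeats=2, seed=1)
        assert report.combined[0] > 95.0
        assert set(report.per_day) == set(htc_split.test.day_keys())

    def test_single_repeat_has_zero_std(self, htc_split):
        params = h.GAParams(population_size=6, epochs=2, seed=2)
        report = h.run_experiment(htc_split, "ga", ga_params=params,
                                  repeats=1, seed=2)
        assert report.combined[1] == 0.0

    def test_same_master_seed_reproduces_report(self, htc_split):
        grid = h.ParamGrid("knn", {"metric": ["euclidean"],
                                   "weights": ["distance"],
                                   "n_neighbors": [1, 5]})
        r1 = h.run_experiment(htc_split, "gs", grid=grid, repeats=2, seed=3)
        r2 = h.run_experiment(htc_split, "gs", grid=grid, repeats=2, seed=3)
        assert r1.combined == r2.combined
        assert r1.per_day == r2.per_day
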