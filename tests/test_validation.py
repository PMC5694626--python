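"""Validation battery: VAF classification, experiment designs, t-maps."""

import numpy as np
import pytest

from eigensynth.phantoms import PhantomSpec, generate_phantom
from eigensynth.validation import (
    ConfigurationError,
    experiment_generalization,
    experiment_resubstitution,
    select_optimal_L,
    tmap_two_sample,
    vaf_cross_validate,
)


@pytest.fixture(scope="module")
def separable_phantom():
    """Two classes with a strong focal effect and near-zero noise."""
    spec = PhantomSpec(shape=(14, 14, 14), class_names=("dis", "ctl"),
                       n_per_class=(25, 25),
                       class_effects={"dis": [((7, 7, 7), 3.0, 1.5)], "ctl": []},
                       latent_dim=2, latent_sd=(0.05, 0.05), noise_sd=0.01,
                       smoothing_fwhm=2.0, seed=21)
    return generate_phantom(spec)[0]


@pytest.fixture(scope="module")
def null_phantom():
    """Two labels drawn from one generating distribution (chance problem)."""
    spec = PhantomSpec(shape=(14, 14, 14), class_names=("p", "q"),
                       n_per_class=(60, 60), class_effects={},
                       latent_dim=3, latent_sd=(0.3, 0.2, 0.1), noise_sd=0.15,
                       smoothing_fwhm=2.0, seed=22)
    return generate_phantom(spec)[0]


class TestVAFCrossValidate:
    def test_identical_distributions_score_at_chance(self, null_phantom):
        rep = vaf_cross_validate(null_phantom, "p", "q", folds=5, seed=0)
        # chance 0.5 within 3 SE of the fold mean
        se = rep.accuracy_sd / np.sqrt(rep.n_folds)
        assert abs(rep.accuracy - 0.5) <= max(3 * se, 0.15)

    def test_separable_classes_are_perfect_every_fold(self, separable_phantom):
        rep = vaf_cross_validate(separable_phantom, "dis", "ctl", folds=5, seed=0)
        assert np.all(rep.fold_accuracy == 1.0)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_label_permutation_collapses_to_chance(self, separable_phantom):
        rng = np.random.default_rng(0)
        shuffled = separable_phantom.subset(np.arange(separable_phantom.n_subjects))
        shuffled.labels = rng.permutation(shuffled.labels)
        rep = vaf_cross_validate(shuffled, "dis", "ctl", folds=5, seed=0)
        assert rep.accuracy <= 0.72  # permutation null oracle

    def test_too_few_subjects_for_folds(self, separable_phantom):
        with pytest.raises(ConfigurationError):
            vaf_cross_validate(separable_phantom, "dis", "ctl", folds=30)

    def test_report_shape_and_chosen_C(self, separable_phantom):
        rep = vaf_cross_validate(separable_phantom, "dis", "ctl", folds=5, seed=0)
        assert rep.n_folds == 5
        assert len(rep.chosen_C) == 5
        assert rep.positive_class == "dis"


class TestGeneralizationExperiment:
    def test_separable_phantom_mvn_generalizes(self, separable_phantom):
        rep = experiment_generalization(separable_phantom, "dis", "ctl",
                                        estimator="mvn", n_per_class=40,
                                        folds=5, seed=1)
        assert rep.accuracy >= 0.95

    def test_signal_outside_retained_subspace_fails(self):
        # class signal much weaker than two dominant shared modes: with L=1
        # the synthetic sets cannot carry it, so accuracy stays near chance
        spec = PhantomSpec(shape=(14, 14, 14), class_names=("dis", "ctl"),
                           n_per_class=(25, 25),
                           class_effects={"dis": [((7, 7, 7), 2.0, 0.12)], "ctl": []},
                           latent_dim=2, latent_sd=(0.8, 0.6), noise_sd=0.02,
                           smoothing_fwhm=2.0, seed=23)
        ds = generate_phantom(spec)[0]
        rep = experiment_generalization(ds, "dis", "ctl", estimator="mvn", L=1,
                                        n_per_class=40, folds=5, seed=1)
        assert rep.accuracy <= 0.75

    def test_no_leakage_from_held_out_fold(self, separable_phantom):
        """Corrupting a fold's held-out subjects changes that fold's metric
        but leaves its synthetic training set bit-identical."""
        artifacts = []
        experiment_generalization(separable_phantom, "dis", "ctl", estimator="mvn",
                                  n_per_class=20, folds=5, seed=2,
                                  fold_artifacts=artifacts)
        target = artifacts[0]
        corrupted = separable_phantom.subset(np.arange(separable_phantom.n_subjects))
        # rows are relative to the two-class subset; classes are already
        # the whole dataset here so indices align
        corrupted.data = corrupted.data.copy()
        corrupted.data[target["test_idx"]] *= 10.0
        artifacts2 = []
        experiment_generalization(corrupted, "dis", "ctl", estimator="mvn",
                                  n_per_class=20, folds=5, seed=2,
                                  fold_artifacts=artifacts2)
        assert np.array_equal(target["synthetic_data"],
                              artifacts2[0]["synthetic_data"])
        assert target["accuracy"] != artifacts2[0]["accuracy"]


class TestResubstitutionExperiment:
    def test_resubstitution_is_perfect_on_separable_data(self, separable_phantom):
        resub, _ = experiment_resubstitution(separable_phantom, "dis", "ctl",
                                             estimator="mvn", n_per_class=20,
                                             n_repeats=2, seed=3)
        assert resub.accuracy == 1.0

    def test_unrelated_synthetic_test_scores_at_chance(self, separable_phantom,
                                                       null_phantom):
        """Negative control: a classifier for the separable problem cannot
        beat chance on synthetic images from an unrelated class structure."""
        from eigensynth.synthesis import fit_generative_model, synthesize_classes
        from eigensynth.validation import _binary_subset, _fit_inner_svm

        sub, y = _binary_subset(separable_phantom, "dis", "ctl")
        search = _fit_inner_svm(sub.data, y, (0.01, 0.1, 1.0, 10.0, 100.0), 5, 0)
        # same geometry, no class effect at all
        spec = PhantomSpec(shape=(14, 14, 14), class_names=("dis", "ctl"),
                           n_per_class=(20, 20), class_effects={},
                           latent_dim=2, latent_sd=(0.3, 0.2), noise_sd=0.1,
                           smoothing_fwhm=2.0, seed=31)
        unrelated = generate_phantom(spec)[0]
        gen = fit_generative_model(unrelated, estimator="mvn")
        synth = synthesize_classes(gen, 100, seed=4)
        acc = np.mean(search.predict(synth.data) == (synth.labels == "dis"))
        assert abs(acc - 0.5) <= 0.2


class TestSelectOptimalL:
    def test_single_candidate_inside_band_is_returned(self, separable_phantom):
        base = vaf_cross_validate(separable_phantom, "dis", "ctl", folds=5, seed=5)
        chosen, sweep = select_optimal_L(separable_phantom, "dis", "ctl",
                                         estimator="mvn", L_grid=(2,),
                                         baseline=base, n_per_class=30,
                                         folds=5, seed=5)
        assert chosen == 2
        assert len(sweep) == 1

    def test_returns_largest_in_band_L(self, separable_phantom):
        base = vaf_cross_validate(separable_phantom, "dis", "ctl", folds=5, seed=5)
        chosen, sweep = select_optimal_L(separable_phantom, "dis", "ctl",
                                         estimator="mvn", L_grid=(2, 5, 10),
                                         baseline=base, n_per_class=30,
                                         folds=5, seed=5)
        in_band = sweep[sweep["in_band"]]
        assert chosen == int(in_band["L"].max())

    def test_empty_band_falls_back_to_closest(self, separable_phantom, caplog):
        from eigensynth.validation import ClassifierReport

        fake = ClassifierReport(accuracy=0.2, sensitivity=0.2, specificity=0.2,
                                accuracy_sd=0.0, sensitivity_sd=0.0,
                                specificity_sd=0.0,
                                fold_accuracy=np.array([0.2]),
                                fold_sensitivity=np.array([0.2]),
                                fold_specificity=np.array([0.2]))
        with caplog.at_level("WARNING"):
            chosen, sweep = select_optimal_L(separable_phantom, "dis", "ctl",
                                             estimator="mvn", L_grid=(2, 4),
                                             baseline=fake, n_per_class=30,
                                             folds=5, seed=5)
        assert chosen in (2, 4)
        assert not sweep["in_band"].any()
        assert "falling back" in caplog.text


class TestTMap:
    def test_same_population_shuffle_yields_no_significance(self):
        rng = np.random.default_rng(11)
        pooled = rng.normal(size=(100, 300))
        perm = rng.permutation(100)
        res = tmap_two_sample(pooled[perm[:50]], pooled[perm[50:]],
                              correction="permutation", n_perm=200, seed=1)
        assert res.n_significant == 0

    def test_power_detects_planted_region(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(50, 300))
        b = rng.normal(size=(50, 300))
        planted = np.arange(20, 40)
        b[:, planted] += 2.0  # 2-SD mean offset
        res = tmap_two_sample(a, b, correction="permutation", n_perm=300, seed=2)
        hits = np.flatnonzero(res.significant_mask)
        assert len(hits) > 0
        assert np.isin(hits, planted).mean() >= 0.9

    def test_zero_variance_groups_give_zero_t(self):
        img = np.ones((2, 50))
        res = tmap_two_sample(img, img.copy(), correction="bonferroni")
        assert np.all(res.t_values == 0)
        assert res.n_significant == 0

    def test_bonferroni_threshold_is_t_quantile(self):
        from scipy import stats

        rng = np.random.default_rng(13)
        a, b = rng.normal(size=(10, 40)), rng.normal(size=(12, 40))
        res = tmap_two_sample(a, b, correction="bonferroni", alpha=0.05)
        assert res.df == 20
        assert res.threshold == pytest.approx(stats.t.ppf(1 - 0.05 / 80, 20))

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            tmap_two_sample(np.ones((1, 10)), np.ones((3, 10)))

    def test_synthetic_tmap_overlaps_original_tmap(self):
        """Class-difference maps computed on synthetic data highlight the
        same voxels as on the original data (Dice >= 0.5)."""
        from eigensynth.synthesis import fit_generative_model, synthesize_classes

        spec = PhantomSpec(shape=(16, 16, 16), class_names=("dis", "ctl"),
                           n_per_class=(100, 100),
                           class_effects={"dis": [((8, 8, 8), 3.0, 0.3)], "ctl": []},
                           latent_dim=2, latent_sd=(0.2, 0.15), noise_sd=0.5,
                           smoothing_fwhm=2.0, seed=41)
        ds = generate_phantom(spec)[0]
        orig = tmap_two_sample(ds.subset(ds.class_rows("dis")),
                               ds.subset(ds.class_rows("ctl")),
                               correction="permutation", n_perm=200, seed=3)
        gen = fit_generative_model(ds, estimator="mvn")
        synth = synthesize_classes(gen, 100, seed=5)
        syn = tmap_two_sample(synth.subset(synth.class_rows("dis")),
                              synth.subset(synth.class_rows("ctl")),
                              correction="permutation", n_perm=200, seed=3)
        inter = (orig.significant_mask & syn.significant_mask).sum()
        denom = orig.significant_mask.sum() + syn.significant_mask.sum()
        assert denom > 0
        assert 2 * inter / denom >= 0.5

    def test_fwe_is_controlled_under_global_null(self):
        """Permutation maxT empirical FWE stays near alpha on null data."""
        rng = np.random.default_rng(14)
        false_positives = 0
        reps = 60
        for _ in range(reps):
            a = rng.normal(size=(10, 80))
            b = rng.normal(size=(10, 80))
            res = tmap_two_sample(a, b, correction="permutation", n_perm=100,
                                  seed=int(rng.integers(2 ** 31)))
            false_positives += res.n_significant > 0
        rate = false_positives / reps
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)
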