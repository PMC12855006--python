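import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aekit.datamodel import AnnotationTable
from aekit.evaluation import (evaluate_embedding, latent_coverage,
                              pca_embedding, random_feature_baseline,
                              reconstruction_r2, robustness,
                              total_correlation, zscore_performance)
from aekit.preprocess import split_dataset


def brute_force_r2(x, x_hat):
    """Independent per-sample variance-ratio computation."""
    vals = []
    for s in range(x.shape[0]):
        resid = x[s] - x_hat[s]
        var_x = np.mean((x[s] - x[s].mean()) ** 2)
        if var_x == 0:
            continue
        vals.append(1 - np.mean((resid - resid.mean()) ** 2) / var_x)
    return np.mean(vals)


class TestReconstructionR2:
    def test_perfect(self, rng):
        x = rng.standard_normal((5, 10))
        assert reconstruction_r2(x, x) == 1.0

    def test_constant_prediction_zero(self, rng):
        x = rng.standard_normal((5, 10))
        x_hat = np.tile(x.mean(axis=1, keepdims=True), (1, 10))
        np.testing.assert_allclose(reconstruction_r2(x, x_hat), 0.0, atol=1e-12)

    def test_worked_example_matches_oracle(self):
        x = np.array([[0.0, 1.0, 2.0]])
        x_hat = np.array([[0.0, 1.0, 5.0]])
        assert reconstruction_r2(x, x_hat) == pytest.approx(-2.0)
        assert reconstruction_r2(x, x_hat) == pytest.approx(
            brute_force_r2(x, x_hat))

    def test_matches_oracle_random(self, rng):
        x = rng.standard_normal((20, 15))
        x_hat = x + rng.standard_normal((20, 15)) * 0.3
        np.testing.assert_allclose(reconstruction_r2(x, x_hat),
                                   brute_force_r2(x, x_hat))

    def test_zero_variance_sample_excluded(self, rng):
        x = np.vstack([np.ones(4), rng.standard_normal(4)])
        with pytest.warns(UserWarning, match="zero-variance"):
            val = reconstruction_r2(x, x)
        assert val == 1.0

    @given(noise=st.floats(0, 2))
    @settings(max_examples=30, deadline=None)
    def test_never_exceeds_one(self, noise):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 8))
        x_hat = x + rng.standard_normal((10, 8)) * noise
        assert reconstruction_r2(x, x_hat) <= 1.0 + 1e-12


class TestLatentCoverage:
    def test_uniform_grid_fill_is_one(self):
        per_dim, mean = latent_coverage(np.array([0.0, 1.0, 2.0, 3.0]))
        assert mean == 1.0

    def test_point_mass_plus_outlier(self):
        per_dim, mean = latent_coverage(np.array([0.0, 0.0, 0.0, 3.0]))
        assert mean == 0.5  # bins {first, last} of 4

    def test_gaussian_2d_below_half(self):
        rng = np.random.default_rng(0)
        _, mean = latent_coverage(rng.standard_normal((10000, 2)))
        assert mean <= 0.5

    def test_degenerate_dimension_reports_1_over_b(self):
        z = np.column_stack([np.zeros(16), np.arange(16.0)])
        per_dim, _ = latent_coverage(z)
        assert per_dim[0] == 1.0 / 4  # b = floor(16^(1/2)) = 4

    def test_affine_rescaling_invariant(self, rng):
        z = rng.standard_normal((500, 2))
        _, m1 = latent_coverage(z)
        _, m2 = latent_coverage(z * np.array([3.0, 0.1]) + np.array([5.0, -2.0]))
        assert m1 == m2

    def test_marginal_mode(self):
        z = np.array([0.0, 0.0, 0.0, 3.0])
        per_dim, mean = latent_coverage(z, mode="marginal")
        assert mean == 0.5

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            latent_coverage(np.array([1.0]))


class TestTotalCorrelation:
    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((100000, 3))
        val = total_correlation(z)
        assert 0 <= val < 0.01

    def test_closed_form_bivariate(self):
        rng = np.random.default_rng(2)
        cov = [[1, 0.8], [0.8, 1]]
        z = rng.multivariate_normal([0, 0], cov, size=100000)
        expected = -0.5 * np.log(1 - 0.8 ** 2)
        assert total_correlation(z) == pytest.approx(expected, abs=0.02)
        assert expected == pytest.approx(0.5108, abs=1e-4)

    def test_duplicated_column_infinite(self, rng):
        a = rng.standard_normal(50)
        assert total_correlation(np.column_stack([a, a])) == np.inf

    def test_exact_identity_is_zero(self):
        z = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 1.0], [-1.0, 1.0],
                      [1.0, -1.0], [-1.0, -1.0]])
        assert total_correlation(z) == 0.0

    def test_constant_column_errors(self):
        with pytest.raises(ValueError):
            total_correlation(np.column_stack([np.ones(10), np.arange(10.0)]))


def _annotated(y_class, y_reg=None):
    ids = [f"S{i:05d}" for i in range(len(y_class))]
    table = pd.DataFrame({"cls": y_class}, index=ids)
    specs = [("cls", "classification")]
    if y_reg is not None:
        table["reg"] = y_reg
        specs.append(("reg", "regression"))
    return AnnotationTable(table=table, task_specs=specs), ids


class TestEvaluateEmbedding:
    def test_separable_classes_perfect_auroc(self, rng):
        n = 80
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        z = np.where((y == "a")[:, None], -5.0, 5.0) + rng.standard_normal((n, 2)) * 0.1
        annotations, ids = _annotated(y)
        split = split_dataset(ids, (0.6, 0.2, 0.2), 0)
        results = evaluate_embedding(z, annotations, split, ids,
                                     algorithms=("linear",))
        assert results[0].performance == 1.0

    def test_permuted_labels_near_chance(self, rng):
        n = 200
        y = rng.permutation(np.array(["a", "b"] * (n // 2)))
        z = rng.standard_normal((n, 2))
        annotations, ids = _annotated(y)
        split = split_dataset(ids, (0.6, 0.2, 0.2), 0)
        results = evaluate_embedding(z, annotations, split, ids,
                                     algorithms=("linear",))
        assert 0.3 < results[0].performance < 0.7

    def test_linear_regression_on_linear_target(self, rng):
        n = 60
        z = rng.standard_normal((n, 3))
        y_reg = z @ np.array([1.0, -2.0, 0.5])
        annotations, ids = _annotated(["a", "b"] * (n // 2), y_reg)
        split = split_dataset(ids, (0.6, 0.2, 0.2), 0)
        results = evaluate_embedding(z, annotations, split, ids,
                                     algorithms=("linear",))
        reg = [r for r in results if r.task == "reg"][0]
        assert reg.performance == pytest.approx(1.0, abs=1e-8)

    def test_single_class_train_skipped(self, rng):
        n = 20
        y = ["a"] * n
        z = rng.standard_normal((n, 2))
        annotations, ids = _annotated(y)
        split = split_dataset(ids, (0.6, 0.2, 0.2), 0)
        with pytest.warns(UserWarning, match="single class"):
            results = evaluate_embedding(z, annotations, split, ids,
                                         algorithms=("linear",))
        assert results == []

    def test_all_three_algorithms_run(self, rng):
        n = 40
        y = ["a", "b"] * (n // 2)
        z = rng.standard_normal((n, 2))
        annotations, ids = _annotated(y)
        split = split_dataset(ids, (0.6, 0.2, 0.2), 0)
        results = evaluate_embedding(z, annotations, split, ids)
        assert {r.algorithm for r in results} == {"linear", "svm", "rf"}


class TestRandomFeatureBaseline:
    def test_returns_r_values_seeded(self, rng):
        n = 60
        x = rng.standard_normal((n, 20))
        annotations, ids = _annotated(["a", "b"] * (n // 2))
        split = split_dataset(ids, (0.6, 0.2, 0.2), 0)
        eta1 = random_feature_baseline(x, 3, annotations, split, ids, "cls",
                                       "classification", "linear", r=5, seed=1)
        eta2 = random_feature_baseline(x, 3, annotations, split, ids, "cls",
                                       "classification", "linear", r=5, seed=1)
        assert eta1.shape == (5,)
        np.testing.assert_array_equal(eta1, eta2)

    def test_all_features_draw_equals_full_performance(self, rng):
        n = 60
        x = rng.standard_normal((n, 4))
        annotations, ids = _annotated(["a", "b"] * (n // 2))
        split = split_dataset(ids, (0.6, 0.2, 0.2), 0)
        eta = random_feature_baseline(x, 4, annotations, split, ids, "cls",
                                      "classification", "linear", r=3, seed=0)
        assert np.all(eta == eta[0])


class TestZScore:
    def test_theta_equal_mean_is_zero(self):
        assert zscore_performance(0.5, np.array([0.4, 0.5, 0.6])) == 0.0

    def test_worked_example(self):
        eta = np.array([0.5, 0.5, 0.6, 0.7, 0.7])  # mean 0.6, pop sd 0.0894
        z = zscore_performance(0.8, eta)
        np.testing.assert_allclose(z, (0.8 - 0.6) / eta.std())
        # the canonical substitution: sd 0.1, mean 0.6, theta 0.8 -> 2.0
        assert zscore_performance(0.8, np.array([0.5, 0.7])) == pytest.approx(2.0)

    def test_degenerate_cohort_missing(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert zscore_performance(0.8, np.array([0.6, 0.6])) is None

    def test_self_draw_mean_near_zero(self, rng):
        reps = 400
        draws = rng.standard_normal(reps) * 0.05 + 0.6
        zs = [zscore_performance(draws[i], np.delete(draws, i)[:5])
              for i in range(reps)]
        assert abs(np.mean(zs)) < 3 / np.sqrt(reps) * 3


class TestRobustness:
    def test_identical_runs_one(self, rng):
        z = rng.standard_normal((30, 3))
        result = robustness([z, z.copy(), z.copy()])
        np.testing.assert_allclose(result.per_dim, 1.0)

    def test_sign_flip_still_one(self, rng):
        z = rng.standard_normal((30, 2))
        result = robustness([z, -z])
        np.testing.assert_allclose(result.per_dim, 1.0)

    def test_independent_runs_near_zero(self, rng):
        runs = [rng.standard_normal((500, 2)) for _ in range(4)]
        assert robustness(runs).mean < 0.15

    def test_symmetric_under_reordering(self, rng):
        runs = [rng.standard_normal((20, 2)) for _ in range(3)]
        a = robustness(runs).per_dim
        b = robustness(list(reversed(runs))).per_dim
        np.testing.assert_allclose(a, b)

    def test_zero_variance_dim_contributes_zero(self, rng):
        z1 = np.column_stack([np.zeros(10), rng.standard_normal(10)])
        z2 = rng.standard_normal((10, 2))
        with pytest.warns(UserWarning, match="zero-variance"):
            result = robustness([z1, z2])
        assert result.per_dim[0] == 0.0


class TestPCABaseline:
    def test_rank1_perfect_reconstruction(self, rng):
        x = np.outer(rng.standard_normal(30), rng.standard_normal(8))
        scores = pca_embedding(x, 1)
        mean = x.mean(axis=0)
        _, _, vt = np.linalg.svd(x - mean, full_matrices=False)
        x_hat = scores @ vt[:1] + mean
        assert reconstruction_r2(x, x_hat) == pytest.approx(1.0)

    def test_scores_uncorrelated(self, rng):
        x = rng.standard_normal((100, 10))
        scores = pca_embedding(x, 3)
        assert total_correlation(scores) == pytest.approx(0.0, abs=1e-8)

    def test_fit_on_train_only(self, rng):
        x = rng.standard_normal((50, 6))
        idx_train = np.arange(30)
        scores = pca_embedding(x, 2, idx_train)
        assert scores.shape == (50, 2)


@pytest.mark.slow
def test_umap_smoke(rng):
    from aekit.evaluation import umap_embedding
    x = rng.standard_normal((60, 5))
    z = umap_embedding(x, 2, seed=0)
    assert z.shape == (60, 2)
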