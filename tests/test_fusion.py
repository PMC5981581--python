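"""z-score normalization, PCA, kernels, SVMs, calibration, and fusion."""

import numpy as np
import pytest

from irispad import fusion
from irispad.errors import TrainingError, ValidationError
from irispad.fusion import (
    FusionWeights,
    KernelSpec,
    calibrate,
    concat,
    fit_norm,
    fit_pca,
    fuse,
    kernel,
    project,
    score,
    select_weights,
    train_svm,
    z_normalize,
)


class TestZScore:
    def test_hand_example_two_points(self):
        stats = fit_norm(np.array([[0.0], [2.0]]))
        assert stats.f_mean[0] == 1.0
        assert stats.sigma[0] == 1.0  # population sd
        assert z_normalize(np.array([0.0]), stats)[0] == -1.0
        assert z_normalize(np.array([2.0]), stats)[0] == 1.0

    def test_mean_vector_maps_to_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 2, (20, 5))
        stats = fit_norm(x)
        assert np.allclose(z_normalize(stats.f_mean, stats), 0.0)

    def test_training_set_standardized(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 4, (50, 8))
        z = z_normalize(x, fit_norm(x))
        assert np.all(np.abs(z.mean(axis=0)) < 1e-8)
        assert np.all(np.abs(z.std(axis=0) - 1) < 1e-6)

    def test_renormalizing_standardized_data_is_identity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5, 2, (30, 4))
        z = z_normalize(x, fit_norm(x))
        # z has mean 0 and sd 1, so normalizing with its own stats is a no-op
        assert np.allclose(z_normalize(z, fit_norm(z)), z, atol=1e-8)

    def test_zero_variance_dimension_passes_through_centered(self):
        x = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
        stats = fit_norm(x)
        assert stats.sigma[1] == 1.0
        z = z_normalize(x, stats)
        assert np.allclose(z[:, 1], 0.0)


class TestConcat:
    def test_hybrid_dimension_and_order(self):
        rng = np.random.default_rng(3)
        f_cnn = rng.normal(size=4096)
        f_mlbp = rng.normal(size=933)
        hybrid = concat(f_cnn, f_mlbp)
        assert hybrid.dim == 5029
        assert hybrid.kind == "hybrid"
        for j in (0, 100, 932):
            assert hybrid.values[4096 + j] == f_mlbp[j]

    def test_empty_second_block(self):
        f = np.arange(5.0)
        assert np.array_equal(concat(f, np.array([])).values, f)


class TestPca:
    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 6))
        model = fit_pca(x, 6)
        recon = project(x, model) @ model.components + model.mean
        assert np.allclose(recon, x, atol=1e-8)

    def test_rank_one_line_first_component(self):
        t = np.linspace(-3, 3, 40)
        x = np.column_stack([t, 2 * t])
        model = fit_pca(x, 2)
        direction = np.array([1.0, 2.0]) / np.sqrt(5)
        assert abs(abs(model.components[0] @ direction) - 1.0) < 1e-10
        assert model.explained_variance[1] < 1e-20

    def test_variances_non_increasing_and_basis_orthonormal(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 10))
        model = fit_pca(x, 8)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(8), atol=1e-8)

    def test_distance_preservation_at_full_rank(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(15, 5))
        proj = project(x, fit_pca(x, 5))
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(proj), pdist(x), atol=1e-8)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            fit_pca(np.zeros((5, 3)), 4)


class TestKernel:
    def test_rbf_self_similarity_is_one(self):
        x = np.array([1.0, -2.0, 3.0])
        assert kernel(x, x, KernelSpec("rbf", gamma=0.5)) == 1.0

    def test_linear_orthogonal_is_zero(self):
        assert kernel(np.array([1.0, 0.0]), np.array([0.0, 5.0]),
                      KernelSpec("linear")) == 0.0

    def test_polynomial_hand_example(self):
        spec = KernelSpec("polynomial", gamma=1.0, coef=1.0, degree=2)
        assert kernel(np.array([1.0, 0.0]), np.array([1.0, 1.0]), spec) == 4.0

    @pytest.mark.parametrize("kind", ["linear", "rbf", "polynomial"])
    def test_symmetry(self, kind):
        rng = np.random.default_rng(7)
        spec = KernelSpec(kind, gamma=0.3, coef=1.0, degree=3)
        for _ in range(100):
            a, b = rng.normal(size=(2, 6))
            assert kernel(a, b, spec) == pytest.approx(kernel(b, a, spec))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            KernelSpec("sigmoid")
        with pytest.raises(ValidationError):
            KernelSpec("rbf", gamma=-1.0)


class TestSvm:
    def test_separable_toy_set_linear(self):
        x = np.array([[0.0, 0], [0, 1], [3, 0], [3, 1]])
        y = np.array([0, 0, 1, 1])
        model = train_svm(x, y, KernelSpec("linear"))
        assert np.array_equal(model.predict(x), y)
        # dual constraint: sum a_i y_i = 0 within solver tolerance
        assert abs(model.dual_coef.sum()) < 1e-6

    def test_xor_needs_nonlinear_kernel(self):
        x = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array([0, 0, 1, 1])
        rbf = train_svm(x, y, KernelSpec("rbf", gamma=2.0), C=100.0)
        assert np.array_equal(rbf.predict(x), y)
        linear = train_svm(x, y, KernelSpec("linear"), C=100.0)
        assert not np.array_equal(linear.predict(x), y)

    def test_mirrored_data_flips_decision_sign(self):
        rng = np.random.default_rng(8)
        x = np.vstack([rng.normal(-2, 0.3, (20, 2)), rng.normal(2, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model = train_svm(x, y, KernelSpec("linear"))
        mirrored = train_svm(-x, y, KernelSpec("linear"))
        probe = np.array([[1.5, 1.5]])
        d1 = model.decision_value(probe)[0]
        d2 = mirrored.decision_value(-probe)[0]
        assert np.sign(d1) == np.sign(d2)
        assert d1 == pytest.approx(d2, rel=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            train_svm(np.zeros((4, 2)), np.zeros(4))


class TestCalibration:
    @pytest.fixture()
    def separable(self):
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(-1, 0.4, (30, 3)), rng.normal(1, 0.4, (30, 3))])
        y = np.array([0] * 30 + [1] * 30)
        model = train_svm(x, y, KernelSpec("rbf"))
        return calibrate(model, x, y), x, y

    def test_midpoint_scores_half(self, separable):
        model, _, _ = separable
        d0 = -model.platt_b / model.platt_a
        s = 1.0 / (1.0 + np.exp(-(model.platt_a * d0 + model.platt_b)))
        assert s == pytest.approx(0.5)

    def test_scores_bounded_and_monotone(self, separable):
        model, x, _ = separable
        d = model.decision_value(x)
        s = score(model, x)
        assert np.all((s >= 0) & (s <= 1))
        order = np.argsort(d)
        assert np.all(np.diff(s[order]) >= -1e-12)

    def test_attack_scores_exceed_bona_fide(self, separable):
        model, x, y = separable
        s = score(model, x)
        assert s[y == 1].mean() > s[y == 0].mean()

    def test_degenerate_decision_values_rejected(self, separable):
        model, _, _ = separable
        with pytest.raises(TrainingError):
            calibrate(model, np.tile(np.zeros(3), (10, 1)), np.arange(10) % 2)


class TestFusion:
    def test_weight_one_returns_first_score(self):
        assert fuse(0.8, 0.3, FusionWeights(1.0, 0.0)) == 0.8

    def test_arithmetic_example(self):
        assert fuse(0.8, 0.4, FusionWeights(0.5, 0.5)) == pytest.approx(0.6)

    def test_equal_scores_fixed_point(self):
        for w1 in (0.0, 0.25, 0.7, 1.0):
            assert fuse(0.42, 0.42, FusionWeights(w1, 1 - w1)) == pytest.approx(0.42)

    def test_convex_bounds_and_exchange_symmetry(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            s1, s2, w1 = rng.random(3)
            s = fuse(s1, s2, FusionWeights(w1, 1 - w1))
            assert min(s1, s2) - 1e-12 <= s <= max(s1, s2) + 1e-12
            swapped = fuse(s2, s1, FusionWeights(1 - w1, w1))
            assert s == pytest.approx(swapped)

    def test_constraint_enforced(self):
        with pytest.raises(ValidationError):
            FusionWeights(0.7, 0.7)
        with pytest.raises(ValidationError):
            FusionWeights(-0.2, 1.2)


class TestSelectWeights:
    def _grid_oracle(self, s1, s2, y):
        best_acc, winners = -1.0, []
        for i in range(101):
            w1 = i / 100.0
            acc = np.mean(((w1 * s1 + (1 - w1) * s2) >= 0.5).astype(int) == y)
            if acc > best_acc:
                best_acc, winners = acc, [w1]
            elif acc == best_acc:
                winners.append(w1)
        return best_acc, winners

    def test_perfect_s1_random_s2(self):
        rng = np.random.default_rng(11)
        y = np.array([0] * 50 + [1] * 50)
        s1 = np.where(y == 1, 0.9, 0.1)
        s2 = rng.random(100)
        w = select_weights(s1, s2, y)
        best_acc, winners = self._grid_oracle(s1, s2, y)
        assert w.w1 in winners
        achieved = np.mean(((w.w1 * s1 + w.w2 * s2) >= 0.5).astype(int) == y)
        assert achieved == best_acc == 1.0

    def test_identical_subsystems_tie_to_half(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        w = select_weights(s, s, y)
        assert (w.w1, w.w2) == (0.5, 0.5)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            w = select_weights(rng.random(30), rng.random(30), y)
            assert w.w1 + w.w2 == pytest.approx(1.0, abs=1e-12)
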