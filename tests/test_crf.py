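import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octseg.crf import (CRFParams, CRFProblem, brute_force_map, gaussian_kernel,
                        make_problem, mean_field_infer, pairwise_potential,
                        refine, sweep_theta, total_energy, unary_argmin,
                        unary_from_proba)


def random_problem(seed, shape=(3, 3)):
    r = np.random.default_rng(seed)
    p1 = r.uniform(0.05, 0.95, shape)
    proba = np.stack([1 - p1, p1], axis=-1)
    return make_problem(proba, r.uniform(0, 1, shape))


class TestUnary:
    def test_certain_probability_zero_potential(self):
        u = unary_from_proba(np.array([[[1.0, 0.0]]]))
        assert u[0, 0, 0] == pytest.approx(0.0)

    def test_uniform_probability_equal_potentials(self):
        u = unary_from_proba(np.array([[[0.5, 0.5]]]))
        assert u[0, 0, 0] == pytest.approx(u[0, 0, 1])

    def test_log_likelihood_value(self):
        u = unary_from_proba(np.array([[[np.exp(-3.0), 1.0]]]))
        assert u[0, 0, 0] == pytest.approx(3.0)


class TestGaussianKernel:
    def test_identical_pixels_give_one(self):
        assert gaussian_kernel((2, 3), (2, 3), 10.0, 10.0, 16, 8) == \
            pytest.approx(1.0)

    def test_characteristic_distance(self):
        # |p_i - p_j|^2 = 2 θα² with equal features → e^{-1}
        ta = 5.0
        d = np.sqrt(2) * ta
        assert gaussian_kernel((0, 0), (0, d), 7.0, 7.0, ta, 8) == \
            pytest.approx(np.exp(-1.0))

    def test_vanishes_at_large_distance(self):
        assert gaussian_kernel((0, 0), (0, 1e4), 0.0, 0.0, 16, 8) < 1e-300

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        pi, pj = r.uniform(0, 20, (2, 2))
        fi, fj = r.uniform(0, 255, 2)
        assert gaussian_kernel(pi, pj, fi, fj, 16, 8) == \
            pytest.approx(gaussian_kernel(pj, pi, fj, fi, 16, 8))


class TestPairwisePotential:
    def test_same_label_costs_nothing(self):
        assert pairwise_potential(1, 1, [0.5], CRFParams()) == 0.0

    def test_weighted_kernel_sum(self):
        params = CRFParams(kernel_weights=(2.0,))
        assert pairwise_potential(0, 1, [0.5], params) == pytest.approx(1.0)

    def test_zero_weights_zero_potential(self):
        params = CRFParams(kernel_weights=(0.0,))
        assert pairwise_potential(0, 1, [0.9], params) == 0.0

    def test_weight_kernel_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_potential(0, 1, [0.5, 0.5], CRFParams(kernel_weights=(1.0,)))


class TestTotalEnergy:
    def test_zero_weights_reduce_to_unary_sum(self):
        prob = random_problem(0)
        params = CRFParams(kernel_weights=(0.0,))
        lab = unary_argmin(prob)
        expected = prob.unary.reshape(-1, 2)[np.arange(9), lab.ravel()].sum()
        assert total_energy(lab, prob, params) == pytest.approx(expected)

    def test_hand_summed_2x2_instance(self):
        # raw (unnormalized) single-kernel model, enumerated over the 6
        # unordered pixel pairs with the standalone kernel function
        unary = np.array([[[0.2, 1.0], [0.7, 0.3]],
                          [[0.9, 0.1], [0.4, 0.6]]])
        feats = np.array([[0.1, 0.5], [0.9, 0.3]])
        prob = CRFProblem(unary=unary, features=feats * 255)
        params = CRFParams(theta_alpha=2.0, theta_beta=40.0,
                           kernel_weights=(1.5,), kernel_normalization="none")
        lab = np.array([[0, 1], [1, 0]])
        coords = [(0, 0), (0, 1), (1, 0), (1, 1)]
        e_hand = sum(unary[c][lab[c]] for c in coords)
        for a in range(4):
            for b in range(a + 1, 4):
                k = gaussian_kernel(coords[a], coords[b],
                                    feats[coords[a]] * 255, feats[coords[b]] * 255,
                                    2.0, 40.0)
                e_hand += 1.5 * k * (lab[coords[a]] != lab[coords[b]])
        assert total_energy(lab, prob, params) == pytest.approx(e_hand)

    def test_uniform_labeling_has_no_pairwise_cost(self):
        prob = random_problem(1)
        params = CRFParams(kernel_weights=(5.0,))
        lab = np.zeros((3, 3), dtype=int)
        expected = prob.unary[..., 0].sum()
        assert total_energy(lab, prob, params) == pytest.approx(expected)

    def test_foreign_labels_rejected(self):
        prob = random_problem(2)
        with pytest.raises(ValueError, match="label"):
            total_energy(np.full((3, 3), 7), prob, CRFParams())


class TestMeanField:
    def test_zero_coupling_equals_unary_argmax(self):
        prob = random_problem(3)
        params = CRFParams(kernel_weights=(0.0,), inference_mode="dense")
        _, lab = mean_field_infer(prob, params)
        assert np.array_equal(lab, unary_argmin(prob))

    def test_marginals_normalized_every_iteration(self):
        prob = random_problem(4)
        for n_iter in (1, 2, 5):
            params = CRFParams(n_iterations=n_iter, inference_mode="dense")
            marg, _ = mean_field_infer(prob, params)
            assert np.allclose(marg.sum(axis=-1), 1.0, atol=1e-9)

    def test_energy_never_above_unary_argmax(self):
        params = CRFParams(inference_mode="dense")
        for seed in range(10):
            prob = random_problem(seed, shape=(4, 4))
            _, lab = mean_field_infer(prob, params)
            assert total_energy(lab, prob, params) <= \
                total_energy(unary_argmin(prob), prob, params) + 1e-9

    def test_hole_filling_at_default_thetas(self):
        img = np.zeros((24, 24))
        img[:, :12], img[:, 12:] = 0.6, 0.15
        truth = np.zeros((24, 24), dtype=int)
        truth[:, 12:] = 1
        proba = np.where(truth[..., None] == np.arange(2), 0.9, 0.1)
        proba[6, 6] = [0.1, 0.9]     # spurious fluid inside the band
        proba[18, 18] = [0.9, 0.1]   # hole inside the fluid pocket
        for mode in ("dense", "filtered"):
            _, lab = refine(proba, img, CRFParams(inference_mode=mode))
            assert np.array_equal(lab, truth), mode

    def test_filtered_agrees_with_dense_on_sharp_image(self, rng):
        img = np.zeros((32, 32))
        img[:, :16], img[:, 16:] = 0.7, 0.15
        truth = (img < 0.5).astype(int)
        p1 = np.clip(truth + rng.normal(0, 0.25, truth.shape), 0.02, 0.98)
        proba = np.stack([1 - p1, p1], axis=-1)
        prob = make_problem(proba, img)
        _, dense = mean_field_infer(prob, CRFParams(inference_mode="dense"))
        _, filt = mean_field_infer(prob, CRFParams(inference_mode="filtered"))
        assert (dense == filt).mean() >= 0.95

    def test_non_finite_unary_rejected(self):
        unary = np.zeros((2, 2, 2))
        unary[0, 0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            CRFProblem(unary=unary, features=np.zeros((2, 2)))


class TestBruteForce:
    def test_single_pixel_takes_cheaper_label(self):
        prob = CRFProblem(unary=np.array([[[0.3, 0.9]]]),
                          features=np.zeros((1, 1)))
        assert brute_force_map(prob, CRFParams())[0, 0] == 0

    def test_zero_coupling_equals_unary_argmax(self):
        prob = random_problem(5)
        params = CRFParams(kernel_weights=(0.0,))
        assert np.array_equal(brute_force_map(prob, params), unary_argmin(prob))

    def test_dominant_coupling_enforces_uniformity(self):
        # one unary dissenter, overwhelming smoothness: uniform labeling wins
        unary = np.zeros((2, 2, 2))
        unary[..., 1] = 0.5            # label 0 preferred everywhere...
        unary[0, 0] = [0.5, 0.0]       # ...except one pixel
        prob = CRFProblem(unary=unary, features=np.zeros((2, 2)))
        params = CRFParams(theta_alpha=10.0, theta_beta=255.0,
                           kernel_weights=(10.0,), kernel_normalization="none")
        assert np.array_equal(brute_force_map(prob, params), np.zeros((2, 2)))

    def test_oversized_problem_rejected(self):
        prob = random_problem(6, shape=(5, 5))
        with pytest.raises(ValueError, match="mean_field_infer"):
            brute_force_map(prob, CRFParams())


class TestSweep:
    @staticmethod
    def instances(n=2):
        out = []
        for seed in range(n):
            r = np.random.default_rng(seed)
            img = np.zeros((16, 16))
            img[:, :8], img[:, 8:] = 0.6, 0.15
            truth = (img < 0.5).astype(np.uint8)
            p1 = np.clip(truth + r.normal(0, 0.2, truth.shape), 0.05, 0.95)
            out.append((np.stack([1 - p1, p1], -1), img, truth))
        return out

    def test_single_point_grid(self):
        res = sweep_theta(self.instances(), [16], [8],
                          CRFParams(n_iterations=3))
        assert len(res.surface) == 1
        assert res.best == res.surface[0]

    def test_surface_values_are_f1_fractions(self):
        res = sweep_theta(self.instances(), [4, 16], [4, 8],
                          CRFParams(n_iterations=2))
        assert len(res.surface) == 4
        assert all(0.0 <= e["mean_f1"] <= 1.0 for e in res.surface)

    def test_fixed_alpha_curve_extraction(self):
        res = sweep_theta(self.instances(1), [4, 16], [4, 8],
                          CRFParams(n_iterations=1))
        curve = res.curve(16.0)
        assert [e["theta_beta"] for e in curve] == [4.0, 8.0]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_theta(self.instances(1), [], [8])
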