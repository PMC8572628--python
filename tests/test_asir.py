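"""Iterative core: the correction formula, fixed points, convergence to the
least-squares solution, and residual-norm behaviour."""

import numpy as np
import pytest
import scipy.sparse as sp

from ctrecon.testing import make_consistent_system
from ctrecon import (
    ImageGrid,
    IterConfig,
    ScanGeometry,
    Sinogram,
    SystemMatrix,
    compute_corrections,
    compute_residuals,
    forward_project,
    initialize,
    reconstruct_iterative,
    update_image,
)
from ctrecon.asir import estimate_projections
from ctrecon.projection import MU_WATER


def toy_matrix(weights: np.ndarray, size: int, spacing: float = 1.0) -> SystemMatrix:
    """Wrap a dense ray-by-pixel weight array as a SystemMatrix."""
    n_rays = weights.shape[0]
    geom = ScanGeometry(n_rays, 1, 10.0 * size, float(size))
    return SystemMatrix(sp.csr_matrix(weights), size, spacing, geom)


def toy_sinogram(y: np.ndarray, matrix: SystemMatrix) -> Sinogram:
    return Sinogram(np.asarray(y, dtype=float).reshape(-1, 1), matrix.geometry)


class TestInitialize:
    def test_zero_init(self):
        mat = toy_matrix(np.array([[1.0, 1.0, 0.0, 1.0]]), 2)
        sino = toy_sinogram([1.0], mat)
        state = initialize(sino, mat, IterConfig(init_mode="zero"))
        assert np.all(state.image.pixels == 0.0)
        assert state.iteration == 0
        assert state.residuals.shape == (1,)

    def test_uniform_init(self):
        mat = toy_matrix(np.eye(4), 2)
        sino = toy_sinogram(np.zeros(4), mat)
        cfg = IterConfig(init_mode="uniform", uniform_value=0.03)
        state = initialize(sino, mat, cfg)
        assert np.all(state.image.pixels == 0.03)

    def test_fbp_init_uses_supplied_image(self):
        mat = toy_matrix(np.eye(4), 2)
        sino = toy_sinogram(np.zeros(4), mat)
        fbp_img = ImageGrid(np.full((2, 2), 0.01), 1.0, "MU")
        state = initialize(sino, mat, IterConfig(init_mode="fbp"), fbp_img)
        np.testing.assert_allclose(state.image.pixels, 0.01)

    def test_fbp_init_without_image_rejected(self):
        mat = toy_matrix(np.eye(4), 2)
        sino = toy_sinogram(np.zeros(4), mat)
        with pytest.raises(ValueError):
            initialize(sino, mat, IterConfig(init_mode="fbp"))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            IterConfig(relaxation=2.0)
        with pytest.raises(ValueError):
            IterConfig(blend_fraction=1.5)
        with pytest.raises(ValueError):
            IterConfig(init_mode="random")
        with pytest.raises(ValueError):
            IterConfig(max_iterations=0)


class TestProjectionAndResiduals:
    def test_two_pixel_toy_estimate(self):
        # weights [1, 1] applied to image [3, 4] -> estimate 7
        mat = toy_matrix(np.array([[1.0, 1.0, 0.0, 0.0]]), 2)
        sino = toy_sinogram([0.0], mat)
        state = initialize(sino, mat, IterConfig(init_mode="zero"))
        state.image = ImageGrid(np.array([[3.0, 4.0], [0.0, 0.0]]), 1.0, "MU")
        assert estimate_projections(state, mat) == pytest.approx([7.0])

    def test_zero_image_estimates_zero(self):
        mat = toy_matrix(np.array([[1.0, 2.0, 3.0, 4.0]]), 2)
        sino = toy_sinogram([5.0], mat)
        state = initialize(sino, mat, IterConfig(init_mode="zero"))
        assert estimate_projections(state, mat) == pytest.approx([0.0])

    def test_consistent_image_has_zero_residuals(self):
        rng = np.random.default_rng(1)
        mat, sino, _, mu_true = make_consistent_system(rng)
        state = initialize(sino, mat, IterConfig(init_mode="zero"))
        state.image = ImageGrid(mu_true, 1.0, "MU")
        res = compute_residuals(sino.flat, estimate_projections(state, mat))
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_residual_arithmetic_and_sign(self):
        assert compute_residuals([10.0], [7.0]) == pytest.approx([3.0])
        assert compute_residuals([5.0], [9.0]) == pytest.approx([-4.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_residuals([1.0, 2.0], [1.0])


class TestCorrections:
    def test_zero_residuals_give_zero_corrections(self):
        mat = toy_matrix(np.array([[1.0, 1.0, 1.0, 1.0]]), 2)
        e = compute_corrections(np.zeros(1), mat, relaxation=1.0)
        np.testing.assert_allclose(e, 0.0)

    def test_single_ray_single_pixel(self):
        # one ray, one pixel, weight w, residual phi -> E = phi / w
        w, phi = 2.5, 0.7
        mat = toy_matrix(np.array([[w, 0.0, 0.0, 0.0]]), 2)
        e = compute_corrections(np.array([phi]), mat, relaxation=1.0)
        assert e[0] == pytest.approx(phi / w)
        assert np.all(e[1:] == 0.0)  # un-crossed pixels untouched

    def test_one_ray_two_equal_pixels_split_the_correction(self):
        w, phi = 1.5, 0.9
        mat = toy_matrix(np.array([[w, w, 0.0, 0.0]]), 2)
        e = compute_corrections(np.array([phi]), mat, relaxation=1.0)
        assert e[0] == pytest.approx(phi / (2 * w))
        assert e[1] == pytest.approx(phi / (2 * w))

    def test_relaxation_scales_linearly(self):
        mat = toy_matrix(np.array([[1.0, 2.0, 0.0, 3.0]]), 2)
        e1 = compute_corrections(np.array([1.0]), mat, relaxation=1.0)
        e_half = compute_corrections(np.array([1.0]), mat, relaxation=0.5)
        np.testing.assert_allclose(e_half, 0.5 * e1)


class TestUpdate:
    def test_zero_corrections_leave_image_unchanged(self):
        mat = toy_matrix(np.array([[1.0, 1.0, 1.0, 1.0]]), 2)
        sino = toy_sinogram([0.1], mat)
        state = initialize(sino, mat, IterConfig(init_mode="uniform", uniform_value=0.025))
        before = state.image.pixels.copy()
        update_image(state, np.zeros(4), sino, mat)
        np.testing.assert_array_equal(state.image.pixels, before)
        assert state.iteration == 1

    def test_additive_update_on_single_pixel(self):
        mat = toy_matrix(np.array([[1.0]]), 1)
        sino = toy_sinogram([2.5], mat)
        state = initialize(sino, mat, IterConfig(init_mode="uniform", uniform_value=2.0))
        update_image(state, np.array([0.5]), sino, mat)
        assert state.image.pixels[0, 0] == pytest.approx(2.5)

    def test_single_ray_system_solved_in_one_relaxation_1_step(self):
        """Kaczmarz exactness: with one ray and lambda = 1, the residual of
        that ray is zero after a single update."""
        mat = toy_matrix(np.array([[1.0, 2.0, 0.5, 1.5]]), 2)
        sino = toy_sinogram([3.0], mat)
        state = initialize(sino, mat, IterConfig(init_mode="zero"))
        corr = compute_corrections(state.residuals, mat, relaxation=1.0)
        update_image(state, corr, sino, mat)
        assert state.residuals[0] == pytest.approx(0.0, abs=1e-12)


class TestReconstructIterative:
    def test_exact_data_is_a_fixed_point(self):
        """Measured = forward(R0) stops after one iteration with R0 back."""
        rng = np.random.default_rng(3)
        mat, sino, _, mu_true = make_consistent_system(rng)
        for lam in (0.5, 1.0, 1.5):
            # start exactly at the solution via the supplied init image
            start = ImageGrid(mu_true, 1.0, "MU")
            cfg = IterConfig(max_iterations=10, tolerance=1e-8, relaxation=lam,
                             init_mode="fbp")
            recon, report = reconstruct_iterative(sino, mat, cfg, fbp_image=start)
            mu_out = MU_WATER * (1.0 + recon.pixels / 1000.0)
            np.testing.assert_allclose(mu_out, mu_true, atol=1e-12)
            assert report.iterations == 1
            assert report.residual_norms[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pseudoinverse_on_full_rank_systems(self):
        """Converged iterate equals the dense least-squares solution on
        random consistent full-rank systems (brute-force pinv oracle)."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            mat, sino, dense, _ = make_consistent_system(rng, full_rank=True)
            cfg = IterConfig(max_iterations=20_000, tolerance=1e-14,
                             relaxation=1.0, init_mode="zero")
            recon, _ = reconstruct_iterative(sino, mat, cfg)
            mu_hat = (MU_WATER * (1.0 + recon.pixels / 1000.0)).reshape(-1)
            x_ls = np.linalg.pinv(dense) @ sino.flat
            rel = np.linalg.norm(mu_hat - x_ls) / np.linalg.norm(x_ls)
            assert rel < 1e-3

    def test_residual_norm_non_increasing_for_small_relaxation(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            mat, sino, _, _ = make_consistent_system(rng, full_rank=False)
            lam = float(rng.uniform(0.1, 1.0))
            cfg = IterConfig(max_iterations=300, tolerance=1e-14,
                             relaxation=lam, init_mode="zero")
            _, report = reconstruct_iterative(sino, mat, cfg)
            norms = np.array(report.residual_norms)
            assert np.all(np.diff(norms) <= 1e-10 * max(1.0, norms[0]))

    def test_blend_mixes_iterative_and_fbp_images(self):
        rng = np.random.default_rng(5)
        mat, sino, _, mu_true = make_consistent_system(rng)
        fbp_img = ImageGrid(np.full(mu_true.shape, 0.02), 1.0, "MU")
        kwargs = dict(max_iterations=500, tolerance=1e-12, relaxation=1.0,
                      init_mode="zero")
        pure, _ = reconstruct_iterative(
            sino, mat, IterConfig(blend_fraction=1.0, **kwargs), fbp_image=fbp_img
        )
        half, _ = reconstruct_iterative(
            sino, mat, IterConfig(blend_fraction=0.5, **kwargs), fbp_image=fbp_img
        )
        fbp_only, _ = reconstruct_iterative(
            sino, mat, IterConfig(blend_fraction=0.0, **kwargs), fbp_image=fbp_img
        )
        np.testing.assert_allclose(fbp_only.pixels, 0.0, atol=1e-9)  # 0.02 = water
        np.testing.assert_allclose(
            half.pixels, 0.5 * pure.pixels + 0.5 * fbp_only.pixels, atol=1e-9
        )

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        mat, sino, _, _ = make_consistent_system(rng)
        cfg = IterConfig(max_iterations=50, tolerance=1e-12, init_mode="zero")
        a, _ = reconstruct_iterative(sino, mat, cfg)
        b, _ = reconstruct_iterative(sino, mat, cfg)
        assert np.array_equal(a.pixels, b.pixels)

    def test_output_is_hounsfield(self):
        rng = np.random.default_rng(13)
        mat, sino, _, _ = make_consistent_system(rng)
        recon, _ = reconstruct_iterative(
            sino, mat, IterConfig(max_iterations=5, init_mode="zero")
        )
        assert recon.value_kind == "HU"
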