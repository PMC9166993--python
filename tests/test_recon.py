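"""Reconstruction algorithms against direct linear-algebra oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

import lungtomo as lt
from lungtomo.recon import kaczmarz_sweep, neighbor_laplacian


def toy_system(A, b, grid_size):
    """Wrap a dense system as (Sinogram, SystemMatrix) on a fake geometry."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    m, n = A.shape
    assert n == grid_size**2
    geo = lt.ProjectionGeometry(angles=(0.0,), detector_count=m,
                                detector_spacing=1.0, beam_model="line")
    M = lt.SystemMatrix(sp.csr_matrix(A), geo, grid_size, 1.0)
    sino = lt.Sinogram(np.asarray(b, dtype=float).reshape(1, m), geo)
    return sino, M


class TestKaczmarzSweep:
    def test_single_equation_solved_in_one_update(self):
        sino, M = toy_system([[1.0, 0.0, 0.0, 0.0]], [5.0], 2)
        x = kaczmarz_sweep(np.zeros(4), M, sino.vector, relaxation=1.0)
        assert x[0] == pytest.approx(5.0) and np.all(x[1:] == 0.0)

    def test_compatible_2x2_converges_to_direct_solve(self):
        # {x + y = 2, x - y = 0} has the unique solution (1, 1)
        A = np.array([[1.0, 1.0], [1.0, -1.0]])
        b = np.array([2.0, 0.0])
        expected = np.linalg.solve(A, b)
        A4 = np.hstack([A, np.zeros((2, 2))])
        sino, M = toy_system(A4, b, 2)
        x = np.zeros(4)
        for _ in range(200):
            x = kaczmarz_sweep(x, M, sino.vector)
        np.testing.assert_allclose(x[:2], expected, atol=1e-10)

    def test_zero_relaxation_leaves_iterate_unchanged(self, rng):
        A = rng.random((3, 4))
        sino, M = toy_system(A, rng.random(3), 2)
        x0 = rng.random(4)
        x = kaczmarz_sweep(x0, M, sino.vector, relaxation=0.0)
        np.testing.assert_array_equal(x, x0)

    def test_all_zero_matrix_returns_input(self):
        sino, M = toy_system(np.zeros((2, 4)), [1.0, 2.0], 2)
        x0 = np.arange(4.0)
        np.testing.assert_array_equal(
            kaczmarz_sweep(x0, M, sino.vector), x0)


class TestART:
    def test_consistent_system_converges(self, rng):
        x_true = rng.random(16)
        A = rng.standard_normal((24, 16))
        sino, M = toy_system(A, A @ x_true, 4)
        res = lt.art_reconstruct(sino, M, lt.ReconConfig(
            algorithm="ART", max_sweeps=2000, stop_tol=1e-7,
            row_norm_cutoff=0.0))
        rel = res.final_residual / np.linalg.norm(sino.vector)
        assert rel < 1e-4 and res.converged

    def test_zero_start_reaches_minimum_norm_solution(self, rng):
        # underdetermined consistent system: oracle = pseudoinverse
        A = rng.standard_normal((8, 16))
        b = A @ rng.random(16)
        sino, M = toy_system(A, b, 4)
        res = lt.art_reconstruct(sino, M, lt.ReconConfig(
            algorithm="ART", max_sweeps=3000, stop_tol=1e-10,
            row_norm_cutoff=0.0))
        expected = np.linalg.pinv(A) @ b
        np.testing.assert_allclose(res.image.vector, expected, rtol=0, atol=1e-6)

    def test_fixed_point_when_starting_from_truth(self, lung64, protocol_setup):
        _, orig, geo, matrix, clean = protocol_setup
        cfg = lt.ReconConfig(algorithm="ART", max_sweeps=2, stop_tol=1e-12,
                             initial_image=orig)
        res = lt.art_reconstruct(clean, matrix, cfg)
        assert res.final_residual / np.linalg.norm(clean.vector) < 1e-10
        np.testing.assert_allclose(res.image.values, orig.values, atol=1e-8)

    def test_cycle_average_beats_last_iterate_on_inconsistent_lines(self):
        # three mutually inconsistent lines in the plane
        A = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        b = np.array([1.0, 1.0, 0.0])
        ls = np.linalg.lstsq(A, b, rcond=None)[0]  # normal-equations oracle
        A4 = np.hstack([A, np.zeros((3, 2))])
        sino, M = toy_system(A4, b, 2)
        base = lt.ReconConfig(algorithm="ART", max_sweeps=500, stop_tol=0.0,
                              row_norm_cutoff=0.0)
        last = lt.art_reconstruct(sino, M, base)
        from dataclasses import replace
        avg = lt.art_reconstruct(sino, M,
                                 replace(base, incompatible_mode="cycle_average"))
        d_last = np.linalg.norm(last.image.vector[:2] - ls)
        d_avg = np.linalg.norm(avg.image.vector[:2] - ls)
        assert d_avg < d_last

    def test_residual_history_length_matches_sweeps(self, rng):
        A = rng.standard_normal((6, 4))
        sino, M = toy_system(A, rng.random(6), 2)
        res = lt.art_reconstruct(sino, M, lt.ReconConfig(
            algorithm="ART", max_sweeps=7, stop_tol=0.0, row_norm_cutoff=0.0))
        assert len(res.residual_history) == 7


class TestSIRT:
    def test_zero_sinogram_zero_start_gives_zero(self, rng):
        A = rng.random((6, 4))
        sino, M = toy_system(A, np.zeros(6), 2)
        res = lt.sirt_reconstruct(sino, M, lt.ReconConfig(
            algorithm="SIRT", max_sweeps=10, stop_tol=0.0))
        assert np.all(res.image.vector == 0.0)

    def test_converges_to_direct_solution_on_consistent_toy(self):
        A = np.array([[1.0, 1.0], [1.0, -1.0]])
        b = np.array([2.0, 0.0])
        A4 = np.hstack([A, np.zeros((2, 2))])
        sino, M = toy_system(A4, b, 2)
        res = lt.sirt_reconstruct(sino, M, lt.ReconConfig(
            algorithm="SIRT", max_sweeps=5000, stop_tol=1e-10))
        np.testing.assert_allclose(res.image.vector[:2],
                                   np.linalg.solve(A, b), atol=1e-4)

    def test_residuals_non_increasing_on_consistent_system(self, rng):
        x_true = rng.random(9)
        A = rng.random((12, 9)) + 0.1
        sino, M = toy_system(A, A @ x_true, 3)
        res = lt.sirt_reconstruct(sino, M, lt.ReconConfig(
            algorithm="SIRT", max_sweeps=100, stop_tol=0.0))
        diffs = np.diff(res.residual_history)
        assert np.all(diffs <= 1e-10)


class TestRLS:
    def test_zero_weight_matches_direct_least_squares(self, rng):
        A = rng.standard_normal((12, 4))
        x_true = rng.random(4)
        sino, M = toy_system(A, A @ x_true, 2)
        res = lt.rls_reconstruct(sino, M, lt.ReconConfig(
            algorithm="RLS", regularization_weight=0.0))
        np.testing.assert_allclose(res.image.vector, x_true, atol=1e-8)

    def test_identity_system_pure_ridge_halves_data(self, rng):
        # minimise (p - x)^2 + x^2  =>  x = p/2
        p = rng.random(4)
        sino, M = toy_system(np.eye(4), p, 2)
        res = lt.rls_reconstruct(sino, M, lt.ReconConfig(
            algorithm="RLS", regularization_weight=1.0, smoothness="none"))
        np.testing.assert_allclose(res.image.vector, p / 2, atol=1e-8)

    def test_solution_norm_shrinks_monotonically_in_weight(self, rng):
        A = rng.standard_normal((10, 9))
        sino, M = toy_system(A, rng.random(10), 3)
        norms = []
        for w in (0.01, 1.0, 100.0, 1e4):
            res = lt.rls_reconstruct(sino, M, lt.ReconConfig(
                algorithm="RLS", regularization_weight=w))
            norms.append(np.linalg.norm(res.image.vector))
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2 * norms[0]

    def test_singular_system_at_zero_weight_reported(self):
        A = np.zeros((4, 4))
        A[0, 0] = 1.0  # rank-1: normal system singular
        sino, M = toy_system(A, [1.0, 0, 0, 0], 2)
        with pytest.raises(np.linalg.LinAlgError, match="regularization"):
            lt.rls_reconstruct(sino, M, lt.ReconConfig(
                algorithm="RLS", regularization_weight=0.0))

    def test_neighbor_laplacian_quadratic_form(self, rng):
        B = neighbor_laplacian(3)
        x = rng.random(9)
        grid = x.reshape(3, 3)
        direct = (np.sum(np.diff(grid, axis=0) ** 2)
                  + np.sum(np.diff(grid, axis=1) ** 2))
        assert x @ (B @ x) == pytest.approx(direct)


class TestFBP:
    def test_zero_sinogram_gives_zero_image(self):
        geo = lt.ProjectionGeometry.uniform(0, 180, 10, detector_count=11)
        sino = lt.Sinogram(np.zeros((18, 11)), geo)
        rec = lt.fbp_reconstruct(sino, geo, "ramp", 8, 1.0)
        assert np.all(rec.values == 0.0)

    def test_disk_interior_value_recovered_within_5pct(self):
        img = lt.render_phantom(lt.disk_spec(128, 40.0))
        geo = lt.ProjectionGeometry.uniform(0, 180, 1, detector_count=185)
        sino = lt.forward_project(img, lt.build_system_matrix(img, geo))
        rec = lt.fbp_reconstruct(sino, geo, "ramp", 128, 1.0)
        x, y = img.pixel_centers()
        inside = x**2 + y**2 <= (0.9 * 40.0) ** 2
        assert abs(rec.values[inside].mean() - 1.0) < 0.05

    def test_angle_reversal_equals_vertical_flip(self):
        img = lt.make_lung_phantom(64, seed=9).image
        D = 95  # odd: detector reversal is exact
        angles = tuple(float(a) for a in range(180))
        geo = lt.ProjectionGeometry(angles=angles, detector_count=D,
                                    detector_spacing=img.pixel_size)
        sino = lt.forward_project(img, lt.build_system_matrix(img, geo))
        rec = lt.fbp_reconstruct(sino, geo, "ramp", 64, img.pixel_size)
        # flipping the image vertically maps view theta (theta > 0) to view
        # 180 - theta with the detector axis reversed; view 0 is unchanged
        flipped = np.empty_like(sino.values)
        flipped[0] = sino.values[0]
        flipped[1:] = sino.values[:0:-1, ::-1]
        flipped_sino = lt.Sinogram(flipped, geo)
        rec_flip = lt.fbp_reconstruct(flipped_sino, geo, "ramp", 64,
                                      img.pixel_size)
        np.testing.assert_allclose(rec_flip.values, rec.values[::-1, :],
                                   atol=1e-8)

    def test_single_view_flagged_limited_angle(self):
        geo = lt.ProjectionGeometry(angles=(0.0,), detector_count=11)
        sino = lt.Sinogram(np.ones((1, 11)), geo)
        with pytest.warns(UserWarning, match="limited-angle"):
            lt.fbp_reconstruct(sino, geo, "ramp", 8, 1.0)

    def test_cross_check_against_skimage_iradon(self):
        from skimage.transform import iradon
        n = 65
        img = lt.render_phantom(lt.disk_spec(n, 20.0))
        angles = tuple(float(a) for a in range(0, 180, 2))
        geo = lt.ProjectionGeometry(angles=angles, detector_count=n,
                                    detector_spacing=1.0, beam_model="line")
        sino = lt.forward_project(img, lt.build_system_matrix(img, geo))
        mine = lt.fbp_reconstruct(sino, geo, "ramp", n, 1.0)
        ref = iradon(sino.values.T, theta=np.asarray(angles), circle=True,
                     filter_name="ramp", interpolation="linear",
                     output_size=n, preserve_range=True)
        x, y = img.pixel_centers()
        interior = x**2 + y**2 <= (0.45 * n) ** 2
        assert np.abs(mine.values - ref)[interior].mean() < 0.02


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(relaxation=0.0), dict(relaxation=2.0), dict(max_sweeps=0),
        dict(algorithm="XYZ"), dict(incompatible_mode="mean"),
        dict(fbp_filter="butterworth"), dict(row_norm_cutoff=1.0),
    ])
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            lt.ReconConfig(**kwargs)

    def test_nan_in_iterates_aborts_with_sweep_number(self, rng):
        A = rng.random((4, 4))
        sino, M = toy_system(A, [1.0, 1, 1, 1], 2)
        # a near-overflow start overflows during the first sweep
        start = lt.ImageGrid(np.full((2, 2), 1e308))
        with pytest.raises(FloatingPointError, match="sweep 1"):
            with np.errstate(invalid="ignore", over="ignore"):
                lt.art_reconstruct(sino, M, lt.ReconConfig(
                    algorithm="ART", max_sweeps=3, row_norm_cutoff=0.0,
                    initial_image=start))
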