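import numpy as np
import pytest

from slsm3d import (
    LevelSetField,
    LSMParams,
    ScalarVolume,
    curvature_term,
    dirac,
    initialize_phi,
    lsm_step,
    region_means,
)
from slsm3d.levelset import DegenerateRegionError
from slsm3d.shape_prior import fit_sphere, prior_field


class TestInitializePhi:
    def test_signed_distance_values(self):
        fld = initialize_phi((21, 21, 21), (10, 10, 10), 5.0)
        assert fld.phi[10, 10, 10] == pytest.approx(5.0)  # center
        assert fld.phi[15, 10, 10] == pytest.approx(0.0)  # on the surface
        assert fld.phi[20, 10, 10] == pytest.approx(-5.0)  # at distance 2r

    def test_sign_semantics(self):
        fld = initialize_phi((16, 16, 16), (8, 8, 8), 4.0)
        x, y, z = np.ogrid[:16, :16, :16]
        d = np.sqrt((x - 8.0) ** 2 + (y - 8.0) ** 2 + (z - 8.0) ** 2)
        assert np.all(fld.phi[d < 4] > 0)
        assert np.all(fld.phi[d > 4] < 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            initialize_phi((8, 8, 8), (4, 4, 4), 0.0)
        with pytest.raises(ValueError):
            initialize_phi((8, 8, 8), (9, 4, 4), 2.0)


class TestDirac:
    def test_closed_form_values(self):
        assert dirac(0.0, 1.0) == pytest.approx(1 / np.pi)
        assert dirac(1.0, 1.0) == pytest.approx(1 / (2 * np.pi))

    def test_even_and_peaked(self, rng):
        phi = rng.normal(scale=4, size=200)
        assert np.allclose(dirac(phi, 1.5), dirac(-phi, 1.5))
        grid = np.linspace(-10, 10, 2001)
        vals = dirac(grid, 2.0)
        assert vals.max() == pytest.approx(1 / (2.0 * np.pi))
        assert np.argmax(vals) == np.argmin(np.abs(grid))
        assert np.all(vals > 0)

    def test_cauchy_normalization(self):
        # integral along an extending phi-line tends to 1
        line = np.linspace(-500, 500, 200001)
        integral = np.trapezoid(dirac(line, 1.5), line)
        assert integral == pytest.approx(1.0, abs=2e-2)

    def test_epsilon_validated(self):
        with pytest.raises(ValueError):
            dirac(0.0, 0.0)


class TestRegionMeans:
    def test_constant_volume(self):
        vol = ScalarVolume(np.full((4, 4, 4), 5.0))
        fld = initialize_phi((4, 4, 4), (2, 2, 2), 1.5)
        assert region_means(vol, fld) == (5.0, 5.0)

    def test_two_voxel_split(self):
        vol = ScalarVolume(np.array([10.0, 2.0]).reshape(2, 1, 1))
        fld = LevelSetField(np.array([1.0, -1.0]).reshape(2, 1, 1))
        assert region_means(vol, fld) == (10.0, 2.0)

    def test_phantom_truth_means(self, clean_phantom):
        vol, truth = clean_phantom
        phi = np.where(truth.data.astype(bool), 1.0, -1.0)
        c1, c2 = region_means(vol, LevelSetField(phi))
        assert c1 == pytest.approx(200.0)
        assert c2 == pytest.approx(50.0)

    def test_surface_voxels_count_as_outside(self):
        vol = ScalarVolume(np.array([9.0, 1.0]).reshape(2, 1, 1))
        fld = LevelSetField(np.array([1.0, 0.0]).reshape(2, 1, 1))
        c1, c2 = region_means(vol, fld)
        assert (c1, c2) == (9.0, 1.0)

    def test_degenerate_region(self):
        vol = ScalarVolume(np.zeros((3, 3, 3)))
        with pytest.raises(DegenerateRegionError):
            region_means(vol, LevelSetField(np.ones((3, 3, 3))))


class TestCurvature:
    def test_flat_plane_is_zero(self):
        x = np.arange(20, dtype=float)
        phi = np.broadcast_to(x[:, None, None] - 10.0, (20, 20, 20)).copy()
        curv = curvature_term(LevelSetField(phi))
        assert np.allclose(curv[2:-2, 2:-2, 2:-2], 0.0, atol=1e-6)

    def test_sphere_matches_minus_two_over_r(self):
        R = 10.0
        fld = initialize_phi((64, 64, 64), (31.5, 31.5, 31.5), R)
        curv = curvature_term(fld)
        x, y, z = np.ogrid[:64, :64, :64]
        d = np.sqrt((x - 31.5) ** 2 + (y - 31.5) ** 2 + (z - 31.5) ** 2)
        interior = (d > 5) & (d < 15)
        expected = -2.0 / d[interior]
        assert np.max(np.abs(curv[interior] - expected) / np.abs(expected)) < 0.05

    def test_scale_invariance(self):
        fld = initialize_phi((32, 32, 32), (15.5, 15.5, 15.5), 8.0)
        doubled = LevelSetField(2.0 * fld.phi)
        assert np.allclose(curvature_term(fld), curvature_term(doubled), atol=1e-3)

    def test_literal_mode_differs_on_generic_field(self, rng):
        fld = LevelSetField(rng.normal(size=(8, 8, 8)))
        assert not np.allclose(
            curvature_term(fld), curvature_term(fld, literal=True)
        )


def oracle_step(u, phi, p, phi_s=None):
    """Independent scalar-loop evolution step (index-clamped differences)."""
    nx, ny, nz = phi.shape
    c1_num = c1_den = c2_num = c2_den = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if phi[i, j, k] > 0:
                    c1_num += u[i, j, k]
                    c1_den += 1
                else:
                    c2_num += u[i, j, k]
                    c2_den += 1
    c1, c2 = c1_num / c1_den, c2_num / c2_den

    def g(i, j, k):
        return phi[min(max(i, 0), nx - 1), min(max(j, 0), ny - 1), min(max(k, 0), nz - 1)]

    dphi = np.empty_like(phi)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                fx = (g(i + 1, j, k) - g(i - 1, j, k)) / 2
                fy = (g(i, j + 1, k) - g(i, j - 1, k)) / 2
                fz = (g(i, j, k + 1) - g(i, j, k - 1)) / 2
                fxx = g(i + 1, j, k) - 2 * g(i, j, k) + g(i - 1, j, k)
                fyy = g(i, j + 1, k) - 2 * g(i, j, k) + g(i, j - 1, k)
                fzz = g(i, j, k + 1) - 2 * g(i, j, k) + g(i, j, k - 1)
                fxy = (g(i + 1, j + 1, k) - g(i + 1, j - 1, k) - g(i - 1, j + 1, k) + g(i - 1, j - 1, k)) / 4
                fxz = (g(i + 1, j, k + 1) - g(i + 1, j, k - 1) - g(i - 1, j, k + 1) + g(i - 1, j, k - 1)) / 4
                fyz = (g(i, j + 1, k + 1) - g(i, j + 1, k - 1) - g(i, j - 1, k + 1) + g(i, j - 1, k - 1)) / 4
                if p.paper_literal_curvature:
                    gam = (fy * fy * fxx + fz * fz * fxx + fx * fx * fyy + fz * fz * fyy
                           + fx * fx * fzz + fy * fy * fzz
                           - 2 * fx * fy * fyz - 2 * fx * fy * fxy - 2 * fx * fz * fxz)
                else:
                    gam = (fy * fy * fxx + fz * fz * fxx + fx * fx * fyy + fz * fz * fyy
                           + fx * fx * fzz + fy * fy * fzz
                           - 2 * fx * fy * fxy - 2 * fy * fz * fyz - 2 * fx * fz * fxz)
                curv = gam / (fx * fx + fy * fy + fz * fz + 1e-8) ** 1.5
                curv = min(max(curv, -3.0), 3.0)
                delta = (p.epsilon / np.pi) / (p.epsilon**2 + phi[i, j, k] ** 2)
                t1 = p.lambda1 * (u[i, j, k] - c1) ** 2
                t2 = p.lambda2 * (u[i, j, k] - c2) ** 2
                if p.paper_literal_signs:
                    force = p.mu * curv - t1 - t2 - p.nu
                else:
                    force = p.mu * curv - t1 + t2 - p.nu
                val = delta * force
                if phi_s is not None and p.tau > 0:
                    val += p.tau * phi_s[i, j, k]
                dphi[i, j, k] = val
    return dphi


class TestLsmStepOracle:
    @pytest.mark.parametrize("literal_signs", [False, True])
    @pytest.mark.parametrize("literal_curv", [False, True])
    @pytest.mark.parametrize("with_prior", [False, True])
    def test_single_step_matches_scalar_loop(self, rng, literal_signs, literal_curv, with_prior):
        u = rng.uniform(0, 1, size=(8, 8, 8))
        phi = rng.normal(scale=2, size=(8, 8, 8))
        p = LSMParams(
            lambda1=1.0, lambda2=2.0, mu=0.3, nu=0.05, epsilon=1.5, dt=0.1,
            tau=0.02 if with_prior else 0.0,
            paper_literal_signs=literal_signs,
            paper_literal_curvature=literal_curv,
        )
        fld = LevelSetField(phi.copy())
        prior = prior_field(fit_sphere(fld), (8, 8, 8)) if with_prior else None
        dphi, nxt = lsm_step(ScalarVolume(u), fld, p, prior)
        expected = oracle_step(u, phi, p, prior.phi_s if prior else None)
        assert np.max(np.abs(dphi - expected)) < 1e-10
        assert np.allclose(nxt.phi, phi + p.dt * expected, atol=1e-10)

    def test_zero_tau_reduces_to_plain_step(self, rng):
        u = rng.uniform(0, 1, size=(6, 6, 6))
        fld = LevelSetField(rng.normal(size=(6, 6, 6)))
        p = LSMParams(tau=0.0)
        prior = prior_field(fit_sphere(fld), (6, 6, 6))
        d_with, _ = lsm_step(ScalarVolume(u), fld, p, prior)
        d_without, _ = lsm_step(ScalarVolume(u), fld, p, None)
        assert np.array_equal(d_with, d_without)

    def test_constant_image_fixed_point(self):
        vol = ScalarVolume(np.full((8, 8, 8), 7.0))
        fld = initialize_phi((8, 8, 8), (4, 4, 4), 2.0)
        p = LSMParams(lambda1=1.0, lambda2=1.0, mu=0.0, nu=0.0, tau=0.0)
        dphi, nxt = lsm_step(vol, fld, p)
        assert np.allclose(dphi, 0.0)
        assert np.array_equal(nxt.phi, fld.phi)
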