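import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monomech import (
    DomainMask,
    ImageFrame,
    IslandRecipe,
    SubstrateSpec,
    VectorField2D,
    dic_displacements,
    drift_correct,
    forward_displacement,
    fttc_inverse,
    gen_island_traction,
    gen_speckle_image,
    greens_kernel,
    median_traction,
    warp_image,
)
from monomech.core import UnitsError

from conftest import PIXEL_SIZE, uniform_shift_field


def boussinesq_reference(kx, ky, E, nu):
    """Half-space surface response written directly from its tensor form."""
    k = np.hypot(kx, ky)
    pref = 2 * (1 + nu) / (E * k**3)
    g11 = pref * ((1 - nu) * k**2 + nu * ky**2)
    g22 = pref * ((1 - nu) * k**2 + nu * kx**2)
    g12 = pref * (-nu * kx * ky)
    return g11, g12, g22


class TestGreensKernel:
    def test_half_space_matches_boussinesq_tensor(self):
        sub = SubstrateSpec(4800.0, 0.49, None)
        kx = np.array([0.02, 0.05, -0.1])
        ky = np.array([0.01, -0.03, 0.08])
        g11, g12, g22 = greens_kernel(kx, ky, sub)
        r11, r12, r22 = boussinesq_reference(kx, ky, 4800.0, 0.49)
        np.testing.assert_allclose(g11, r11, rtol=1e-12)
        np.testing.assert_allclose(g12, r12, rtol=1e-12)
        np.testing.assert_allclose(g22, r22, rtol=1e-12)

    def test_finite_thickness_converges_monotonically(self):
        sub_f = SubstrateSpec(4800.0, 0.49, 100.0)
        sub_i = SubstrateSpec(4800.0, 0.49, None)
        khs = np.linspace(0.2, 30.0, 300)
        k = khs / 100.0
        gf, _, _ = greens_kernel(k, np.zeros_like(k), sub_f)
        gi, _, _ = greens_kernel(k, np.zeros_like(k), sub_i)
        ratio = gf / gi
        assert np.all(np.diff(ratio) >= -1e-12)
        assert np.all(ratio <= 1.0 + 1e-12)  # finite layer is stiffer
        assert abs(ratio[khs >= 10][0] - 1.0) < 0.01

    def test_small_kh_suppression(self):
        # thin-layer response is strongly suppressed relative to half-space
        sub_f = SubstrateSpec(4800.0, 0.3, 100.0)
        sub_i = SubstrateSpec(4800.0, 0.3, None)
        k = np.array([0.001])  # kh = 0.1
        gf, _, _ = greens_kernel(k, np.zeros(1), sub_f)
        gi, _, _ = greens_kernel(k, np.zeros(1), sub_i)
        assert gf[0] / gi[0] < 0.2

    @settings(max_examples=50, deadline=None)
    @given(
        kx=st.floats(-1.0, 1.0),
        ky=st.floats(-1.0, 1.0),
        nu=st.floats(0.0, 0.49),
        h=st.floats(10.0, 1000.0),
    )
    def test_positive_definite_for_random_wavevectors(self, kx, ky, nu, h):
        if np.hypot(kx, ky) < 1e-3:
            return
        sub = SubstrateSpec(4800.0, nu, h)
        g11, g12, g22 = greens_kernel(np.array([kx]), np.array([ky]), sub)
        tr = g11[0] + g22[0]
        det = g11[0] * g22[0] - g12[0] ** 2
        assert tr > 0 and det > 0


class TestForwardModel:
    def test_zero_traction_zero_displacement(self, substrate):
        T = VectorField2D(np.zeros((32, 32)), np.zeros((32, 32)), 8.0, "Pa")
        u = forward_displacement(T, substrate)
        assert np.abs(u.vx).max() == 0
        assert u.units == "um"

    def test_linearity(self, substrate):
        rng = np.random.default_rng(2)
        t1 = VectorField2D(rng.standard_normal((32, 32)),
                           rng.standard_normal((32, 32)), 8.0, "Pa")
        t2 = VectorField2D(rng.standard_normal((32, 32)),
                           rng.standard_normal((32, 32)), 8.0, "Pa")
        combo = t1.with_values(2 * t1.vx - 3 * t2.vx, 2 * t1.vy - 3 * t2.vy)
        u = forward_displacement(combo, substrate)
        u1 = forward_displacement(t1, substrate)
        u2 = forward_displacement(t2, substrate)
        np.testing.assert_allclose(u.vx, 2 * u1.vx - 3 * u2.vx, atol=1e-12)

    def test_contractile_island_pulls_inward(self, island, substrate):
        traction, _, mask = island
        u = forward_displacement(traction, substrate)
        gx, gy = traction.node_coords()
        cx, cy = gx.mean(), gy.mean()
        rx, ry = gx - cx, gy - cy
        r = np.hypot(rx, ry)
        radial = (u.vx * rx + u.vy * ry) / np.where(r > 0, r, 1.0)
        inside = mask.mask & (r > 50)
        assert np.mean(radial[inside] < 0) > 0.99  # displacement points inward
        mag = np.hypot(u.vx, u.vy)
        ring = (r > 350) & (r < 500)
        far = r > 900
        assert mag[ring].mean() > 3 * mag[far].mean()

    def test_units_enforced(self, substrate):
        bad = VectorField2D(np.zeros((8, 8)), np.zeros((8, 8)), 8.0, "um")
        with pytest.raises(UnitsError):
            forward_displacement(bad, substrate)


class TestFttcInverse:
    def test_zero_displacement_zero_traction(self, substrate):
        u = VectorField2D(np.zeros((32, 32)), np.zeros((32, 32)), 8.0, "um")
        T = fttc_inverse(u, substrate)
        assert np.abs(T.vx).max() == 0
        assert T.units == "Pa"

    def test_island_round_trip(self, island, substrate):
        traction, _, _ = island
        u = forward_displacement(traction, substrate)
        back = fttc_inverse(u, substrate)
        err = np.sqrt(np.mean((back.vx - traction.vx) ** 2
                              + (back.vy - traction.vy) ** 2))
        ref = np.sqrt(np.mean(traction.vx**2 + traction.vy**2))
        assert err / ref < 0.02

    def test_doubling_modulus_doubles_traction(self, substrate):
        rng = np.random.default_rng(3)
        u = VectorField2D(rng.standard_normal((32, 32)) * 0.1,
                          rng.standard_normal((32, 32)) * 0.1, 8.0, "um")
        t1 = fttc_inverse(u, substrate)
        stiff = SubstrateSpec(2 * substrate.youngs_modulus_pa,
                              substrate.poisson_ratio,
                              substrate.thickness_um)
        t2 = fttc_inverse(u, stiff)
        np.testing.assert_allclose(t2.vx, 2 * t1.vx, rtol=1e-10)

    def test_translation_equivariance(self, substrate):
        rng = np.random.default_rng(4)
        base = np.zeros((48, 48))
        base[16:28, 18:30] = rng.standard_normal((12, 12)) * 0.05
        u1 = VectorField2D(base, 0.5 * base, 8.0, "um")
        u2 = VectorField2D(np.roll(base, (3, 5), (0, 1)),
                           np.roll(0.5 * base, (3, 5), (0, 1)), 8.0, "um")
        # on the unpadded (periodic) operator the identity is exact
        t1 = fttc_inverse(u1, substrate, pad_factor=1.0)
        t2 = fttc_inverse(u2, substrate, pad_factor=1.0)
        np.testing.assert_allclose(
            np.roll(t1.vx, (3, 5), (0, 1)), t2.vx, atol=1e-8
        )

    def test_noise_robust_median_with_cutoff(self, island, substrate):
        traction, _, mask = island
        u = forward_displacement(traction, substrate)
        rng = np.random.default_rng(5)
        snr = 10.0
        sigma = np.sqrt(np.mean(u.vx**2 + u.vy**2)) / snr
        noisy = u.with_values(
            u.vx + rng.normal(0, sigma, u.shape),
            u.vy + rng.normal(0, sigma, u.shape),
        )
        clean_med = median_traction(fttc_inverse(u, substrate), mask)
        cutoff = 4 * traction.grid_spacing
        noisy_med = median_traction(
            fttc_inverse(noisy, substrate, cutoff_wavelength=cutoff), mask
        )
        assert abs(noisy_med - clean_med) / clean_med < 0.15


class TestDic:
    def test_identical_images_zero_field(self, speckle_frame):
        d = dic_displacements(speckle_frame, speckle_frame)
        assert np.abs(d.field.vx).max() < 0.02 * PIXEL_SIZE
        assert np.all((d.quality >= 0) & (d.quality <= 1))

    def test_uniform_subpixel_shift_recovered(self, speckle_frame):
        u = uniform_shift_field(speckle_frame.shape, (2.25, -1.0))
        warped = warp_image(speckle_frame, u)
        d = dic_displacements(speckle_frame, warped)
        vx = d.field.vx / PIXEL_SIZE
        vy = d.field.vy / PIXEL_SIZE
        rms = np.sqrt(np.mean((vx - 2.25) ** 2 + (vy + 1.0) ** 2))
        assert rms < 0.1

    def test_smooth_field_recovered(self, substrate):
        # forward-model displacement from a compact traction patch
        rec = IslandRecipe(radius_um=150.0, grid_shape=(128, 128),
                           grid_spacing_um=PIXEL_SIZE * 4)
        traction, _, _ = gen_island_traction(rec)
        traction = traction.with_values(traction.vx * 5, traction.vy * 5)
        u = forward_displacement(traction, substrate)
        frame = gen_speckle_image((512, 512), 0.08, PIXEL_SIZE, seed=21)
        u_px = VectorField2D(u.vx, u.vy, u.grid_spacing, "um")
        warped = warp_image(frame, u_px)
        d = dic_displacements(frame, warped, window=32, step=16)
        gx, gy = d.field.node_coords()
        from monomech.core import bilinear_sample

        ex = bilinear_sample(u.vx, gx, gy, u.grid_spacing)
        ey = bilinear_sample(u.vy, gx, gy, u.grid_spacing)
        err = np.sqrt(np.mean((d.field.vx - ex) ** 2 + (d.field.vy - ey) ** 2))
        ref = np.sqrt(np.mean(ex**2 + ey**2))
        assert err / ref < 0.05

    def test_window_larger_than_image_rejected(self, speckle_frame):
        small = ImageFrame(np.asarray(speckle_frame.image)[:24, :24],
                           PIXEL_SIZE)
        with pytest.raises(ValueError, match="window"):
            dic_displacements(small, small, window=32)

    def test_flat_images_rejected(self):
        flat = ImageFrame(np.zeros((128, 128)), PIXEL_SIZE)
        with pytest.raises(ValueError):
            dic_displacements(flat, flat)


class TestPostprocessing:
    def test_drift_correction_removes_uniform_offset(self):
        rng = np.random.default_rng(6)
        vx = rng.standard_normal((32, 32)) * 0.01 + 0.5
        vy = rng.standard_normal((32, 32)) * 0.01 - 0.3
        fld = VectorField2D(vx, vy, 8.0, "um")
        far = np.zeros((32, 32), dtype=bool)
        far[:4, :] = True
        out = drift_correct(fld, far)
        assert abs(np.median(out.vx[far])) < 1e-12
        assert abs(np.median(out.vy[far])) < 1e-12

    def test_median_traction_uniform_field(self):
        mag = 10.0
        T = VectorField2D(np.full((16, 16), mag / np.sqrt(2)),
                          np.full((16, 16), mag / np.sqrt(2)), 8.0, "Pa")
        mask = DomainMask(np.ones((16, 16), dtype=bool), 8.0)
        assert median_traction(T, mask) == pytest.approx(mag)

    def test_median_traction_disk_closed_form(self, island):
        # |T|(r) = 2 sigma0 r / R^2 is monotone, so the median over the disk
        # sits at the median radius R/sqrt(2): 2 sigma0/(R sqrt 2) = 2.83 Pa
        traction, _, mask = island
        expected = 2 * 1.0 / (500.0 * np.sqrt(2)) * 1000.0
        assert median_traction(traction, mask) == pytest.approx(
            expected, rel=0.02
        )

    def test_single_node_mask(self, island):
        traction, _, _ = island
        m = np.zeros(traction.shape, dtype=bool)
        m[100, 80] = True
        mask = DomainMask(m, traction.grid_spacing)
        expected = float(np.hypot(traction.vx[100, 80], traction.vy[100, 80]))
        assert median_traction(traction, mask) == pytest.approx(expected)
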