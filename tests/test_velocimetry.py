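import numpy as np
import pytest
from scipy.integrate import solve_ivp

from monomech import (
    AcquisitionSpec,
    ImageFrame,
    VectorField2D,
    classify_phase,
    dense_flow,
    integrate_trajectories,
    summarize_speed,
    warp_image,
)
from monomech.core import bilinear_sample

from conftest import PIXEL_SIZE, uniform_shift_field

BACKENDS = ["ilk", "xcorr"]


class TestDenseFlow:
    def test_frame_vs_itself_zero(self, speckle_frame):
        for method in BACKENDS:
            fl = dense_flow(speckle_frame, speckle_frame, method=method)
            assert np.abs(fl.vx).max() < 0.05 * PIXEL_SIZE
            assert np.abs(fl.vy).max() < 0.05 * PIXEL_SIZE

    @pytest.mark.parametrize("method", BACKENDS)
    @pytest.mark.parametrize("shift", [(3.0, 0.0), (5.0, 0.0), (2.25, -1.0)])
    def test_rigid_translation_recovered(self, speckle_frame, method, shift):
        # both backends must recover translations to < 0.2 px interior median
        u = uniform_shift_field(speckle_frame.shape, shift)
        warped = warp_image(speckle_frame, u)
        fl = dense_flow(speckle_frame, warped, method=method)
        ny, nx = fl.shape
        sl = (slice(ny // 4, 3 * ny // 4), slice(nx // 4, 3 * nx // 4))
        mx = np.median(fl.vx[sl]) / PIXEL_SIZE
        my = np.median(fl.vy[sl]) / PIXEL_SIZE
        assert np.hypot(mx - shift[0], my - shift[1]) < 0.2

    def test_small_rotation_matches_analytic_field(self, speckle_frame):
        theta = np.deg2rad(0.5)
        H, W = speckle_frame.shape
        jj, ii = np.meshgrid(np.arange(W), np.arange(H))
        xc, yc = (W - 1) / 2.0, (H - 1) / 2.0
        ux = ((np.cos(theta) - 1) * (jj - xc) - np.sin(theta) * (ii - yc))
        uy = (np.sin(theta) * (jj - xc) + (np.cos(theta) - 1) * (ii - yc))
        u = VectorField2D(ux * PIXEL_SIZE, uy * PIXEL_SIZE, PIXEL_SIZE, "um")
        warped = warp_image(speckle_frame, u)
        fl = dense_flow(speckle_frame, warped, method="ilk")
        gx, gy = fl.node_coords()
        ex = ((np.cos(theta) - 1) * (gx - xc * PIXEL_SIZE)
              - np.sin(theta) * (gy - yc * PIXEL_SIZE))
        ey = (np.sin(theta) * (gx - xc * PIXEL_SIZE)
              + (np.cos(theta) - 1) * (gy - yc * PIXEL_SIZE))
        ny, nx = fl.shape
        sl = (slice(ny // 4, 3 * ny // 4), slice(nx // 4, 3 * nx // 4))
        rms = np.sqrt(
            np.mean((fl.vx - ex)[sl] ** 2 + (fl.vy - ey)[sl] ** 2)
        ) / PIXEL_SIZE
        assert rms < 0.2

    def test_textureless_input_raises(self):
        flat = ImageFrame(np.full((64, 64), 7.0), PIXEL_SIZE)
        with pytest.raises(ValueError, match="textureless"):
            dense_flow(flat, flat)

    def test_intensity_rescaling_invariance(self, speckle_frame):
        u = uniform_shift_field(speckle_frame.shape, (2.0, 1.0))
        warped = warp_image(speckle_frame, u)
        fl1 = dense_flow(speckle_frame, warped)
        bright_a = ImageFrame(np.asarray(speckle_frame.image) * 3.0, PIXEL_SIZE)
        bright_b = ImageFrame(np.asarray(warped.image) * 3.0, PIXEL_SIZE)
        fl2 = dense_flow(bright_a, bright_b)
        assert np.median(np.abs(fl1.vx - fl2.vx)) < 0.02 * PIXEL_SIZE


def _uniform_flows(n, shape, vx_um, vy_um, spacing=10.0):
    return [
        VectorField2D(np.full(shape, vx_um), np.full(shape, vy_um),
                      spacing, "um")
        for _ in range(n)
    ]


class TestTrajectories:
    def test_constant_flow_exact_euler_displacement(self):
        flows = _uniform_flows(5, (20, 20), 1.5, -0.5)
        spec = AcquisitionSpec(0.65, 6.0, 6)
        traj = integrate_trajectories(flows, spec, seed_spacing_um=30.0)
        disp = traj.positions[:, -1] - traj.positions[:, 0]
        retained = ~traj.exited
        np.testing.assert_allclose(disp[retained, 0], 5 * 1.5, atol=1e-9)
        np.testing.assert_allclose(disp[retained, 1], 5 * -0.5, atol=1e-9)

    def test_zero_flow_stationary(self):
        flows = _uniform_flows(4, (16, 16), 0.0, 0.0)
        traj = integrate_trajectories(flows, AcquisitionSpec(0.65, 6.0, 5))
        assert np.all(traj.positions[:, 0] == traj.positions[:, -1])
        assert not traj.exited.any()

    def test_steady_swirl_matches_fine_integrator(self):
        # gentle rigid rotation: Euler-per-frame vs continuous ODE solution
        shape, spacing = (40, 40), 10.0
        jj, ii = np.meshgrid(np.arange(40), np.arange(40))
        xc = yc = 39 / 2 * spacing
        omega = 2e-3  # rad per interval
        ux = -omega * (ii * spacing - yc)
        uy = omega * (jj * spacing - xc)
        fl = VectorField2D(ux, uy, spacing, "um")
        flows = [fl] * 20
        spec = AcquisitionSpec(0.65, 6.0, 21)
        traj = integrate_trajectories(flows, spec, seed_spacing_um=60.0)

        def rhs(_t, p):
            return [
                bilinear_sample(ux, p[0], p[1], spacing)[()],
                bilinear_sample(uy, p[0], p[1], spacing)[()],
            ]

        k = traj.n_traj // 2
        sol = solve_ivp(rhs, (0, 20), traj.positions[k, 0], rtol=1e-9,
                        atol=1e-9)
        path_len = np.linalg.norm(
            np.diff(traj.positions[k], axis=0), axis=1
        ).sum()
        err = np.linalg.norm(traj.positions[k, -1] - sol.y[:, -1])
        assert err < 0.01 * path_len

    def test_exiting_trajectories_flagged_not_dropped(self):
        flows = _uniform_flows(30, (8, 8), 20.0, 0.0)  # strong drift off-grid
        traj = integrate_trajectories(flows, AcquisitionSpec(0.65, 6.0, 31))
        assert traj.exited.any()
        assert traj.positions.shape[0] == traj.exited.size

    def test_empty_flow_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            integrate_trajectories([], AcquisitionSpec(0.65, 6.0, 1))


class TestSpeedSummary:
    def test_displacement_per_frame_converts_to_um_per_h(self):
        # 0.3 um per 6-min interval is 3 um/h
        flows = _uniform_flows(10, (20, 20), 0.3, 0.0)
        traj = integrate_trajectories(flows, AcquisitionSpec(0.65, 6.0, 11))
        summ = summarize_speed(traj)
        assert summ.fov_mean_speed == pytest.approx(3.0)

    def test_back_and_forth_nonzero_step_speed(self):
        # net displacement zero, path-based speed 2d per two intervals
        shape = (20, 20)
        fwd = _uniform_flows(1, shape, 0.3, 0.0)[0]
        back = _uniform_flows(1, shape, -0.3, 0.0)[0]
        flows = [fwd, back] * 5
        traj = integrate_trajectories(flows, AcquisitionSpec(0.65, 6.0, 11))
        summ = summarize_speed(traj)
        assert summ.fov_mean_speed == pytest.approx(3.0)
        assert np.allclose(summ.per_traj_net_speed[~traj.exited], 0.0)

    def test_time_reversal_leaves_step_speed_unchanged(self):
        flows = _uniform_flows(6, (16, 16), 0.4, 0.2)
        rev = [f.with_values(-f.vx, -f.vy) for f in flows[::-1]]
        spec = AcquisitionSpec(0.65, 6.0, 7)
        s1 = summarize_speed(integrate_trajectories(flows, spec))
        s2 = summarize_speed(integrate_trajectories(rev, spec))
        assert s1.fov_mean_speed == pytest.approx(s2.fov_mean_speed)

    def test_speed_map_on_seed_grid(self):
        flows = _uniform_flows(3, (20, 20), 0.3, 0.0)
        traj = integrate_trajectories(flows, AcquisitionSpec(0.65, 6.0, 4),
                                      seed_spacing_um=30.0)
        summ = summarize_speed(traj)
        assert summ.speed_map.shape == traj.seed_grid_shape
        assert summ.speed_map.units == "um/h"


class TestClassifyPhase:
    @pytest.mark.parametrize(
        "speed,expected",
        [(5.0, "migratory"), (1.8, "migratory"), (1.79, "jammed"),
         (0.0, "jammed")],
    )
    def test_threshold_inclusive(self, speed, expected):
        assert classify_phase(speed) == expected

    def test_monotone_in_speed(self):
        speeds = np.linspace(0, 5, 50)
        phases = [classify_phase(s) == "migratory" for s in speeds]
        assert phases == sorted(phases)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            classify_phase(-0.1)
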