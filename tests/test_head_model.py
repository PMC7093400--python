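import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megfocus import (
    SphereModel,
    build_sensor_array,
    build_source_grid,
    compute_leadfield,
    dipole_field,
    fit_overlapping_spheres,
)
from megfocus.head_model import ConfigurationError, DegenerateFitError, global_fit_residual

from .oracles import gradiometer_signal_oracle


class TestSensorArray:
    def test_channels_on_helmet_sphere(self):
        arr = build_sensor_array(160, 0.12, 0.55, 0.05)
        radii = np.linalg.norm(arr.positions_inner, axis=1)
        assert arr.n_channels == 160
        assert np.all(np.abs(radii - 0.12) < 1e-12)
        assert np.allclose(
            arr.positions_outer, arr.positions_inner + 0.05 * arr.axes, atol=1e-15
        )

    def test_small_array_angular_separation(self):
        # equal-area spiral keeps even 4 channels well separated
        arr = build_sensor_array(4, 0.12, 0.55, 0.05)
        u = arr.positions_inner / np.linalg.norm(arr.positions_inner, axis=1, keepdims=True)
        cos = u @ u.T
        np.fill_diagonal(cos, -1.0)
        assert np.degrees(np.arccos(cos.max())) > 30.0

    @pytest.mark.parametrize("bad", [dict(cap_fraction=0.0), dict(n_channels=3), dict(helmet_radius=-1.0)])
    def test_invalid_geometry_rejected(self, bad):
        kwargs = dict(n_channels=16, helmet_radius=0.12, cap_fraction=0.55, baseline=0.05)
        kwargs.update(bad)
        with pytest.raises(ConfigurationError):
            build_sensor_array(**kwargs)


class TestSourceGrid:
    def test_clipping_and_determinism(self, sphere):
        g1 = build_source_grid(sphere, spacing=0.007, n_regions=34, margin=0.005)
        g2 = build_source_grid(sphere, spacing=0.007, n_regions=34, margin=0.005)
        assert np.all(g1.eccentricities < 0.085)
        assert np.array_equal(g1.region_labels, g2.region_labels)
        # every region non-empty, labels within 1..34
        assert set(np.unique(g1.region_labels)) == set(range(1, 35))

    def test_too_coarse_grid_rejected(self, sphere):
        # 5-cm spacing leaves fewer lattice points than regions
        with pytest.raises(ConfigurationError):
            build_source_grid(sphere, spacing=0.05, n_regions=34, margin=0.005)


class TestDipoleField:
    def test_radial_source_is_silent(self, sphere, sensors):
        pos = np.array([0.03, 0.02, 0.04])
        radial = pos / np.linalg.norm(pos)
        tang = np.cross(radial, [0.0, 0.0, 1.0])
        tang /= np.linalg.norm(tang)
        b_rad = dipole_field(pos, radial * 1e-8, sphere, sensors)
        b_tan = dipole_field(pos, tang * 1e-8, sphere, sensors)
        assert np.linalg.norm(b_rad) < 1e-10 * np.linalg.norm(b_tan)

    def test_depth_attenuation(self, sphere, sensors):
        tang = np.array([0.0, 1.0, 0.0]) * 1e-8
        shallow = dipole_field([0.07, 0.0, 0.0], tang, sphere, sensors)
        deep = dipole_field([0.03, 0.0, 0.0], tang, sphere, sensors)
        assert np.sqrt(np.mean(shallow**2)) > np.sqrt(np.mean(deep**2))

    def test_agrees_with_complex_step_oracle(self, sphere, sensors):
        rng = np.random.default_rng(42)
        for _ in range(100):
            pos = rng.uniform(-0.05, 0.05, 3)
            if np.linalg.norm(pos) < 0.005:
                pos = np.array([0.03, 0.01, 0.02])
            mom = rng.standard_normal(3) * 1e-8
            impl = dipole_field(pos, mom, sphere, sensors)
            ref = gradiometer_signal_oracle(pos, mom, sensors, sphere.center)
            assert np.linalg.norm(impl - ref) < 1e-10 * np.linalg.norm(ref)

    def test_mirror_symmetry(self, sphere):
        # symmetric 8-channel array: mirror through y=0 permutes channels
        theta = np.deg2rad([30, 30, 60, 60])
        phi = np.deg2rad([45, -45, 135, -135])
        axes = np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        inner = 0.12 * axes
        arr_inner = np.vstack([inner, inner * [1, -1, 1]])
        arr_axes = np.vstack([axes, axes * [1, -1, 1]])
        from megfocus import SensorArray

        arr = SensorArray(arr_inner, arr_inner + 0.05 * arr_axes, arr_axes, 0.05)
        pos = np.array([0.02, 0.03, 0.04])
        mom = np.array([1.0, 2.0, -1.0]) * 1e-8
        sig = dipole_field(pos, mom, sphere, arr)
        sig_m = dipole_field(pos * [1, -1, 1], mom * [-1, 1, -1], sphere, arr)
        perm = np.r_[4:8, 0:4]
        assert np.allclose(sig_m, sig[perm], rtol=1e-10)

    def test_source_outside_or_at_center_rejected(self, sphere, sensors):
        with pytest.raises(ConfigurationError):
            dipole_field([0.1, 0.0, 0.0], [0, 1e-8, 0], sphere, sensors)
        with pytest.raises(ConfigurationError):
            dipole_field([0.0, 0.0, 0.0], [0, 1e-8, 0], sphere, sensors)

    def test_overlapping_spheres_use_channel_centers(self, sensors):
        base = SphereModel(center=np.zeros(3), radius=0.09)
        shifted = np.tile(np.array([0.005, 0.0, 0.0]), (sensors.n_channels, 1))
        over = SphereModel(center=np.zeros(3), radius=0.09, per_channel_centers=shifted)
        pos, mom = np.array([0.0, 0.03, 0.04]), np.array([1e-8, 0, 0])
        b_global = dipole_field(pos, mom, base, sensors)
        b_over = dipole_field(pos, mom, over, sensors)
        assert not np.allclose(b_global, b_over, rtol=1e-3, atol=0.0)


class TestLeadField:
    def test_matches_dipole_field_and_linearity(self, grid, sensors, sphere, leadfield):
        v = 17
        mom = np.array([3.0, -1.0, 2.0]) * 1e-9
        direct = dipole_field(grid.voxel_positions[v], mom, sphere, sensors)
        one_hot = np.zeros(3 * grid.n_voxels)
        one_hot[3 * v : 3 * v + 3] = mom
        assert np.allclose(leadfield.matrix @ one_hot, direct, rtol=1e-12)
        assert np.allclose(leadfield.matrix @ (2 * one_hot), 2 * direct, rtol=1e-12)

    def test_blocks_have_rank_two(self, grid, leadfield):
        for v in range(grid.n_voxels):
            s = np.linalg.svd(leadfield.block(v), compute_uv=False)
            assert s[2] < 1e-10 * s[0]

    def test_depth_attenuation_along_radial_line(self, sphere, sensors):
        # column norms shrink monotonically toward the sphere center
        direction = np.array([0.3, 0.5, 0.8])
        direction /= np.linalg.norm(direction)
        norms = []
        for ecc in np.linspace(0.08, 0.01, 8):
            from megfocus.head_model import gradiometer_gain

            norms.append(np.linalg.norm(gradiometer_gain(ecc * direction, sphere, sensors)))
        assert np.all(np.diff(norms) < 1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    ecc=st.floats(0.01, 0.08),
    theta=st.floats(0.0, np.pi),
    phi=st.floats(0.0, 2 * np.pi),
)
def test_silent_radial_source_property(ecc, theta, phi):
    sphere = SphereModel(center=np.zeros(3), radius=0.09)
    sensors = build_sensor_array(16, 0.12, 0.55, 0.05)
    pos = ecc * np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    radial = pos / np.linalg.norm(pos)
    from megfocus.head_model import gradiometer_gain

    gain = gradiometer_gain(pos, sphere, sensors)
    assert np.linalg.norm(gain @ radial) < 1e-10 * np.linalg.norm(gain)


class TestSphereFitting:
    @staticmethod
    def _sphere_points(center, radius, n=80, seed=1):
        rng = np.random.default_rng(seed)
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        u[:, 2] = np.abs(u[:, 2])  # upper scalp
        return center + radius * u

    def test_exact_sphere_recovers_center_everywhere(self, sensors):
        center = np.array([0.002, -0.001, 0.01])
        pts = self._sphere_points(center, 0.09)
        model = fit_overlapping_spheres(sensors, pts)
        assert np.linalg.norm(model.center - center) < 1e-9
        assert abs(model.radius - 0.09) < 1e-9
        assert np.all(np.linalg.norm(model.per_channel_centers - center, axis=1) < 1e-9)

    def test_too_few_points_rejected(self, sensors):
        pts = self._sphere_points(np.zeros(3), 0.09)[:3]
        with pytest.raises(DegenerateFitError):
            fit_overlapping_spheres(sensors, pts)

    def test_coplanar_points_rejected(self, sensors):
        pts = np.random.default_rng(0).uniform(-0.05, 0.05, (30, 3))
        pts[:, 2] = 0.04
        with pytest.raises(DegenerateFitError):
            fit_overlapping_spheres(sensors, pts)

    def test_spheroid_scalp_gives_distinct_channel_centers(self, sensors):
        pts = self._sphere_points(np.zeros(3), 1.0)
        pts = pts * np.array([0.09, 0.09, 0.10])  # prolate spheroid
        model = fit_overlapping_spheres(sensors, pts)
        spread = np.ptp(model.per_channel_centers, axis=0)
        assert spread.max() > 1e-4
        assert global_fit_residual(pts) > 1e-4
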