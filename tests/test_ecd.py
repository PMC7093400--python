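import numpy as np
import pytest

from megfocus import (
    DipoleFit,
    apply_acceptance,
    best_gof_cluster,
    fit_single_dipole,
    scan_spike,
)
from megfocus.ecd import coarse_scan_operators
from megfocus.simulate import make_spike_waveform


def _tangential(pos):
    radial = pos / np.linalg.norm(pos)
    t = np.cross(radial, [0.3, 0.1, 0.9])
    return t / np.linalg.norm(t)


def _fit(b, sensors, sphere, grid, scan_ops):
    return fit_single_dipole(b, sensors, sphere, grid, scan_ops=scan_ops)


@pytest.fixture(scope="module")
def scan_ops(leadfield160):
    return coarse_scan_operators(leadfield160)


class TestFitSingleDipole:
    def test_noiseless_round_trip(self, grid, sensors160, sphere, leadfield160, scan_ops):
        rng = np.random.default_rng(21)
        for v in rng.integers(0, grid.n_voxels, size=10):
            pos = grid.voxel_positions[v]
            mom = _tangential(pos) * 120e-9
            b = leadfield160.block(v) @ mom
            fit = _fit(b, sensors160, sphere, grid, scan_ops)
            assert np.linalg.norm(fit.position - pos) < 1e-3
            assert fit.gof_pct > 99.9
            assert fit.q_nam == pytest.approx(120.0, rel=0.05)

    def test_gof_scale_invariant(self, grid, sensors160, sphere, leadfield160, scan_ops):
        v = 40
        rng = np.random.default_rng(22)
        b = leadfield160.block(v) @ (_tangential(grid.voxel_positions[v]) * 1e-7)
        b = b + rng.standard_normal(b.size) * np.abs(b).max() * 0.3
        f1 = _fit(b, sensors160, sphere, grid, scan_ops)
        f5 = _fit(5.0 * b, sensors160, sphere, grid, scan_ops)
        assert f1.gof_pct == pytest.approx(f5.gof_pct, abs=1e-9)

    def test_noisy_snapshot_gof_below_100(self, grid, sensors160, sphere, leadfield160, scan_ops):
        rng = np.random.default_rng(23)
        v = 100
        b = leadfield160.block(v) @ (_tangential(grid.voxel_positions[v]) * 1e-7)
        b = b + rng.standard_normal(b.size) * np.abs(b).max()  # SNR ~ 1
        fit = _fit(b, sensors160, sphere, grid, scan_ops)
        assert fit.gof_pct < 100.0

    def test_pure_noise_rejected(self, grid, sensors160, sphere, scan_ops):
        rng = np.random.default_rng(24)
        fit = _fit(rng.standard_normal(160) * 1e-13, sensors160, sphere, grid, scan_ops)
        if fit.gof_pct <= 70.0:
            assert not fit.accepted

    def test_zero_snapshot_rejected(self, grid, sensors160, sphere, scan_ops):
        with pytest.raises(ValueError):
            _fit(np.zeros(160), sensors160, sphere, grid, scan_ops)

    def test_depth_degrades_position_error(self, grid, sensors160, sphere, scan_ops):
        # matched absolute noise: deep fits err more than superficial ones
        from megfocus.head_model import gradiometer_gain

        rng = np.random.default_rng(25)
        noise_level = None
        errors = {}
        for ecc in (0.07, 0.03):
            pos = np.array([0.0, 0.0, ecc])
            gain = gradiometer_gain(pos, sphere, sensors160)
            b0 = gain @ (_tangential(np.array([0.0, 0.3, 1.0])) * 150e-9)
            if noise_level is None:
                noise_level = np.sqrt(np.mean(b0**2)) / 2.0  # SNR 2 at 0.07
            errs = []
            for _ in range(15):
                b = b0 + rng.standard_normal(b0.size) * noise_level
                fit = _fit(b, sensors160, sphere, grid, scan_ops)
                errs.append(np.linalg.norm(fit.position - pos))
            errors[ecc] = np.mean(errs)
        assert errors[0.03] > errors[0.07]


class TestScanSpike:
    def test_fit_count_arithmetic(self, grid, sensors160, sphere, leadfield160, scan_ops):
        sr = 1000.0
        v = 50
        topo = leadfield160.block(v) @ (_tangential(grid.voxel_positions[v]) * 1e-7)
        w50 = np.outer(topo, np.ones(50))  # 50-ms window
        fits = scan_spike(w50, sr, sensors160, sphere, grid, scan_ops=scan_ops)
        assert len(fits) == 11
        w4 = np.outer(topo, np.ones(4))  # shorter than one 5-ms step
        fits4 = scan_spike(w4, sr, sensors160, sphere, grid, scan_ops=scan_ops)
        assert len(fits4) == 1 and fits4[0].time_s == 0.0

    def test_best_gof_near_amplitude_peak(self, grid, sensors160, sphere, leadfield160, scan_ops):
        sr = 1000.0
        v = 80
        wave = make_spike_waveform(0.08, sr)
        topo = leadfield160.block(v) @ (_tangential(grid.voxel_positions[v]) * 1e-7)
        rng = np.random.default_rng(26)
        w = np.outer(topo, wave)
        w = w + rng.standard_normal(w.shape) * np.abs(w).max() * 0.05
        fits = scan_spike(w, sr, sensors160, sphere, grid, scan_ops=scan_ops)
        best = max(fits, key=lambda f: f.gof_pct)
        t_peak = np.argmax(np.abs(wave)) / sr
        assert abs(best.time_s - t_peak) <= 0.005


class TestAcceptance:
    @staticmethod
    def _fit(gof, q_nam):
        return DipoleFit(
            time_s=0.0,
            position=np.array([0.0, 0.0, 0.05]),
            moment=np.array([q_nam * 1e-9, 0.0, 0.0]),
            gof_pct=gof,
            accepted=False,
        )

    @pytest.mark.parametrize(
        "gof,q,expected",
        [
            (70.0, 120.0, False),   # boundary GOF: strict inequality
            (95.0, 49.0, False),    # moment below the physiological window
            (95.0, 501.0, False),
            (85.0, 120.0, True),
            (70.1, 50.0, True),     # inclusive moment bounds
            (70.1, 500.0, True),
        ],
    )
    def test_acceptance_boundaries(self, gof, q, expected):
        accepted = apply_acceptance([self._fit(gof, q)])
        assert (len(accepted) == 1) is expected

    def test_idempotent(self):
        fits = [self._fit(80.0, 100.0), self._fit(60.0, 100.0)]
        once = apply_acceptance(fits)
        twice = apply_acceptance(once)
        assert [f.gof_pct for f in once] == [f.gof_pct for f in twice]


class TestBestGofCluster:
    @staticmethod
    def _fit_at(grid, voxel, gof):
        return DipoleFit(
            time_s=0.0,
            position=grid.voxel_positions[voxel],
            moment=np.array([1e-7, 0.0, 0.0]),
            gof_pct=gof,
            accepted=True,
        )

    def test_clear_mode_wins(self, grid):
        region_voxels = {}
        for v in range(grid.n_voxels):
            region_voxels.setdefault(grid.region_labels[v], v)
        r_major = list(region_voxels)[0]
        r_other = list(region_voxels)[1]
        fits = {
            f"IED{k}": [self._fit_at(grid, region_voxels[r_major], 90.0)] for k in range(6)
        }
        fits["IED6"] = [self._fit_at(grid, region_voxels[r_other], 95.0)]
        diag = best_gof_cluster(fits, grid)
        assert diag.focus_region == r_major
        assert sum(diag.region_counts.values()) == 7

    def test_evenly_scattered_not_available(self, grid):
        region_voxels = {}
        for v in range(grid.n_voxels):
            region_voxels.setdefault(int(grid.region_labels[v]), v)
        six = list(region_voxels.values())[:6]
        fits = {f"IED{k}": [self._fit_at(grid, six[k], 90.0)] for k in range(6)}
        diag = best_gof_cluster(fits, grid)
        assert diag.focus_region == 0

    def test_no_accepted_fits_not_available(self, grid):
        diag = best_gof_cluster({"IED0": [], "IED1": []}, grid)
        assert diag.focus_region == 0
        assert diag.region_counts == {}

    def test_best_fit_is_max_gof_per_ied(self, grid):
        v = 10
        fits = {
            "IED0": [self._fit_at(grid, v, 80.0), self._fit_at(grid, v, 92.0)],
            "IED1": [self._fit_at(grid, v, 85.0)],
            "IED2": [self._fit_at(grid, v, 88.0)],
        }
        diag = best_gof_cluster(fits, grid)
        assert [f.gof_pct for f in diag.best_fits] == [92.0, 85.0, 88.0]
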