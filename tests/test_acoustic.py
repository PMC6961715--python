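import numpy as np
import pytest
from scipy.optimize import curve_fit

from qpat.acoustic import (AcousticConfig, closed_surface_mask,
                           limited_view_correction, planar_sensor_mask,
                           propagate_forward, smooth_and_threshold,
                           time_reversal)
from qpat.grids import MultispectralImage, VoxelGrid


def _gaussian_blob(n, pitch, center_frac=(0.5, 0.5, 0.5), sigma=0.6):
    x = np.arange(n) * pitch
    xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
    cx, cy, cz = [f * x[-1] for f in center_frac]
    return np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2)
                  / (2 * sigma**2))


class TestSolverPhysics:
    def test_cfl_limit_enforced(self):
        with pytest.raises(ValueError, match="CFL"):
            AcousticConfig(cfl=0.5)

    def test_plane_wave_dispersion(self):
        """Numerical phase speed within 0.1% of c0 at 4-voxel wavelength.

        Periodic domain (no PML); a standing plane-wave mode oscillates at
        omega = c0 k, so fitting the recorded cosine yields the numerical
        sound speed.
        """
        n = 32
        pitch = 0.2
        cfg = AcousticConfig(pml_size=0)
        m = 8  # mode index -> wavelength n/m = 4 voxels
        dx = pitch * 1e-3
        k = 2 * np.pi * m / (n * dx)
        x = np.arange(n) * dx
        p0 = np.cos(k * x)[:, None, None] * np.ones((1, n, n))
        grid = VoxelGrid(p0, pitch)
        mask = np.zeros((n, n, n), dtype=bool)
        mask[0, 0, 0] = True
        series = propagate_forward(grid, cfg, mask, n_steps=200)
        t = np.arange(series.n_t) * series.dt
        amp0 = series.pressure[0, 0]

        def model(t, omega, a, phi):
            return a * np.cos(omega * t + phi)

        popt, _ = curve_fit(model, t, series.pressure[0],
                            p0=(cfg.c0 * k, amp0, 0.0))
        c_num = abs(popt[0]) / k
        assert abs(c_num / cfg.c0 - 1.0) < 1e-3

    def test_point_absorber_arrival_time(self):
        """Peak arrives at the sensor after distance / c0."""
        n = 32
        pitch = 0.2
        cfg = AcousticConfig(pml_size=8)
        p0 = np.zeros((n, n, n))
        p0[n // 2, n // 2, 20] = 1.0
        grid = VoxelGrid(p0, pitch)
        mask = np.zeros((n, n, n), dtype=bool)
        mask[n // 2, n // 2, 0] = True
        series = propagate_forward(grid, cfg, mask)
        expected = 20 * pitch * 1e-3 / cfg.c0
        s = series.pressure[0]
        # a point source arrives as an N-wave; its centre (the zero
        # crossing between the compression and rarefaction lobes) marks
        # the geometric time of flight
        i_pos = int(np.argmax(s))
        i_neg = i_pos + int(np.argmin(s[i_pos:]))
        seg = s[i_pos:i_neg + 1]
        i_cross = i_pos + int(np.argmin(np.abs(seg)))
        assert abs(i_cross * series.dt - expected) <= 1.5 * series.dt

    def test_zero_p0_gives_zero_series_and_zero_reconstruction(self):
        n = 16
        cfg = AcousticConfig(pml_size=4)
        grid = VoxelGrid(np.zeros((n, n, n)), 0.2)
        series = propagate_forward(grid, cfg)
        assert np.all(series.pressure == 0)
        recon = time_reversal(series, cfg)
        assert np.all(recon.values == 0)

    def test_amplitude_linearity(self):
        n = 16
        cfg = AcousticConfig(pml_size=4)
        blob = _gaussian_blob(n, 0.2)
        s1 = propagate_forward(VoxelGrid(blob, 0.2), cfg)
        s2 = propagate_forward(VoxelGrid(2 * blob, 0.2), cfg)
        assert np.allclose(s2.pressure, 2 * s1.pressure, atol=1e-12)


class TestTimeReversal:
    def test_closed_surface_roundtrip_high_fidelity(self):
        n = 24
        cfg = AcousticConfig(pml_size=8)
        blob = _gaussian_blob(n, 0.2, sigma=0.7)
        grid = VoxelGrid(blob, 0.2)
        series = propagate_forward(grid, cfg, closed_surface_mask(grid.shape))
        recon = time_reversal(series, cfg)
        corr = np.corrcoef(blob.ravel(), recon.values.ravel())[0, 1]
        assert corr > 0.99

    def test_planar_aperture_attenuates_deep_absorber(self):
        n = 24
        cfg = AcousticConfig(pml_size=8)
        blob = _gaussian_blob(n, 0.2, center_frac=(0.5, 0.5, 0.75),
                              sigma=0.4)
        grid = VoxelGrid(blob, 0.2)
        series = propagate_forward(grid, cfg, planar_sensor_mask(grid.shape))
        recon = time_reversal(series, cfg)
        assert recon.values.max() < blob.max()

    def test_grid_mismatch_rejected(self):
        n = 16
        cfg = AcousticConfig(pml_size=4)
        grid = VoxelGrid(_gaussian_blob(n, 0.2), 0.2)
        series = propagate_forward(grid, cfg)
        wrong = VoxelGrid(np.zeros((n, n, n)), 0.3)
        with pytest.raises(ValueError, match="incompatible"):
            time_reversal(series, cfg, grid=wrong)


class TestSmoothAndThreshold:
    def test_constant_volume_unchanged(self):
        msi = MultispectralImage.from_arrays(
            [800.0], np.full((1, 12, 12, 12), 3.0), 0.2)
        out = smooth_and_threshold(msi, 0.01)
        assert np.allclose(out[800.0].values, 3.0)

    def test_delta_on_pedestal_preserves_sum(self):
        """The k-space Hann window has unit DC gain: sums are invariant."""
        vals = np.ones((1, 16, 16, 16))
        vals[0, 8, 8, 8] += 10.0
        msi = MultispectralImage.from_arrays([800.0], vals, 0.2)
        out = smooth_and_threshold(msi, 0.001)
        assert out[800.0].values.sum() == pytest.approx(vals.sum(),
                                                        rel=1e-6)
        # spike spreads to its neighbours but the peak stays at the spike
        assert out[800.0].values.argmax() == vals[0].argmax()
        assert out[800.0].values.max() < vals.max()

    def test_threshold_floor_is_fraction_of_max(self):
        vals = np.zeros((1, 10, 10, 10))
        vals[0, 5, 5, 5] = 50.0
        msi = MultispectralImage.from_arrays([800.0], vals, 0.2)
        out = smooth_and_threshold(msi, 0.01)
        peak = out[800.0].values.max()
        assert out[800.0].values.min() == pytest.approx(0.01 * peak)

    def test_all_zero_input_rejected(self):
        msi = MultispectralImage.from_arrays([800.0],
                                             np.zeros((1, 8, 8, 8)), 0.2)
        with pytest.raises(ValueError, match="all-zero|non-positive"):
            smooth_and_threshold(msi)


class TestLimitedViewCorrection:
    def _planar_measurement(self, n=20, pitch=0.2, cfg=None):
        cfg = cfg or AcousticConfig(pml_size=6)
        blob = (_gaussian_blob(n, pitch, center_frac=(0.5, 0.5, 0.7),
                               sigma=0.5)
                + 0.6 * _gaussian_blob(n, pitch,
                                       center_frac=(0.4, 0.5, 0.25),
                                       sigma=0.5))
        grid = VoxelGrid(blob, pitch)
        series = propagate_forward(grid, cfg, planar_sensor_mask(grid.shape))
        recon = time_reversal(series, cfg)
        msi = MultispectralImage(
            [700.0, 800.0], [recon, recon.like(0.5 * recon.values)])
        return blob, msi, cfg

    def test_correction_amplifies_deep_signal(self):
        blob, msi, cfg = self._planar_measurement()
        eta, corrected = limited_view_correction(msi, cfg)
        k_deep = int(0.7 * blob.shape[2])
        before = msi.volumes[0].values[:, :, k_deep - 2:k_deep + 3].max()
        after = corrected.volumes[0].values[:, :, k_deep - 2:k_deep + 3].max()
        assert after > before
        assert np.all(eta.eta.values > 0)

    def test_spectral_ratio_preserved_exactly(self):
        _blob, msi, cfg = self._planar_measurement()
        _eta, corrected = limited_view_correction(msi, cfg)
        m0, m1 = msi.volumes[0].values, msi.volumes[1].values
        c0, c1 = corrected.volumes[0].values, corrected.volumes[1].values
        safe = np.abs(m1) > 1e-6 * np.abs(m1).max()
        assert np.allclose(c0[safe] / c1[safe], m0[safe] / m1[safe])

    def test_closed_surface_eta_near_unity(self):
        """Full-aperture acquisition loses nothing: eta ~ 1."""
        n = 20
        cfg = AcousticConfig(pml_size=6)
        blob = _gaussian_blob(n, 0.2, sigma=0.8) + 0.05
        grid = VoxelGrid(blob, 0.2)
        mask = closed_surface_mask(grid.shape)
        series = propagate_forward(grid, cfg, mask)
        recon = time_reversal(series, cfg)
        msi = MultispectralImage([800.0], [recon])
        eta, corrected = limited_view_correction(msi, cfg, sensor_mask=mask)
        core = np.abs(eta.eta.values[4:-4, 4:-4, 4:-4] - 1.0)
        assert np.median(core) < 0.05

    def test_second_pass_eta_closer_to_unity(self):
        """Applying the correction twice: the second eta is nearer 1."""
        _blob, msi, cfg = self._planar_measurement(n=20)
        eta1, corrected = limited_view_correction(msi, cfg)
        eta2, _ = limited_view_correction(corrected, cfg)
        med1 = np.median(np.abs(eta1.eta.values - 1.0))
        med2 = np.median(np.abs(eta2.eta.values - 1.0))
        assert med2 < med1
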