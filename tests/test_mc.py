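import numpy as np
import pytest
from scipy import stats

from qpat.grids import VoxelGrid
from qpat.mc import (McConfig, fresnel_boundary, fresnel_reflectance,
                     launch_positions, simulate_fluence)
from qpat.phantom import BeamProfile
from qpat.validation import (beer_lambert_check, diffusion_check,
                             uniform_slab_phantom)


class TestFresnel:
    def test_normal_incidence_water_to_sensor(self):
        """R = ((n1 - n2)/(n1 + n2))^2 at normal incidence."""
        expected = ((1.33 - 1.5) / (1.33 + 1.5)) ** 2
        assert fresnel_reflectance(1.0, 1.33, 1.5) == pytest.approx(expected)

    def test_matched_indices_transmit_unchanged(self, rng):
        d = np.array([0.3, 0.4, np.sqrt(1 - 0.25)])
        reflected, new_d = fresnel_boundary(d, 1.4, 1.4, rng,
                                            normal=(0, 0, 1))
        assert not reflected
        assert np.allclose(new_d, d)

    def test_total_internal_reflection_beyond_critical_angle(self, rng):
        # n1 > n2, grazing: sin(theta_c) = n2/n1 = 0.6667
        sin_i = 0.9
        d = np.array([sin_i, 0.0, np.sqrt(1 - sin_i**2)])
        assert fresnel_reflectance(d[2], 1.5, 1.0) == 1.0
        reflected, new_d = fresnel_boundary(d, 1.5, 1.0, rng,
                                            normal=(0, 0, 1))
        assert reflected
        assert np.allclose(new_d, [sin_i, 0.0, -d[2]])

    def test_refraction_obeys_snell(self):
        class AlwaysTransmit:
            def random(self):
                return 1.0  # never below reflectance < 1

        sin_i = 0.5
        d = np.array([sin_i, 0.0, np.sqrt(1 - sin_i**2)])
        _, new_d = fresnel_boundary(d, 1.33, 1.5, AlwaysTransmit(),
                                    normal=(0, 0, 1))
        assert np.linalg.norm(new_d) == pytest.approx(1.0)
        assert new_d[0] == pytest.approx(1.33 / 1.5 * sin_i)


class TestLaunchPositions:
    def test_delta_beam_all_identical(self, rng):
        beam = BeamProfile.delta((3.0, 4.0), pitch=0.1)
        pos, dirs = launch_positions(beam, 500, rng)
        assert np.ptp(pos[:, 0]) < 0.1 and np.ptp(pos[:, 1]) < 0.1
        assert np.all(pos[:, 2] == 0)
        assert np.all(dirs == [0, 0, 1])

    def test_gaussian_sample_diameter_within_2pct(self, rng):
        beam = BeamProfile.gaussian((64, 64), 0.5, d_1e2=13.0)
        pos, _ = launch_positions(beam, 1_000_000, rng)
        # 1/e^2 diameter of a Gaussian beam is 4 sigma of the samples
        d_est = 4.0 * pos[:, 0].std()
        assert abs(d_est / 13.0 - 1.0) < 0.02

    def test_gaussian_histogram_chi_square_gof(self, rng):
        beam = BeamProfile.gaussian((16, 16), 1.0, d_1e2=13.0)
        n = 1_000_000
        pos, _ = launch_positions(beam, n, rng)
        ix = np.clip(((pos[:, 0] - beam.origin_xy[0] + beam.pitch / 2)
                      / beam.pitch).astype(int), 0, 15)
        iy = np.clip(((pos[:, 1] - beam.origin_xy[1] + beam.pitch / 2)
                      / beam.pitch).astype(int), 0, 15)
        obs = np.zeros((16, 16))
        np.add.at(obs, (ix, iy), 1)
        expected = beam.profile / beam.profile.sum() * n
        keep = expected > 5
        chi2 = float((((obs - expected) ** 2 / expected)[keep]).sum())
        dof = int(keep.sum()) - 1
        assert chi2 < stats.chi2.ppf(0.99, dof)

    def test_uniform_disk_support(self, rng):
        n = 33
        pitch = 0.25
        x = (np.arange(n) - n // 2) * pitch
        xx, yy = np.meshgrid(x, x, indexing="ij")
        radius = 2.0
        prof = (xx**2 + yy**2 <= radius**2).astype(float)
        beam = BeamProfile(prof, pitch, origin_xy=(x[0], x[0]))
        pos, _ = launch_positions(beam, 20_000, rng)
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert r.max() <= radius + pitch


class TestTransportPhysics:
    def test_beer_lambert_depth_profile(self):
        """Non-scattering absorber follows exp(-mu_a z) exactly.

        Continuous weight attenuation makes the ballistic estimate
        deterministic, so the tolerance is far inside the 3-sigma band.
        """
        report = beer_lambert_check(n_photons=5000, seed=0)
        assert report["max_rel_err"] < 1e-10

    def test_no_absorber_conserves_energy(self):
        """mu_a = 0 with matched boundaries: everything launched exits."""
        ph = uniform_slab_phantom((20, 20, 20), 0.25, mu_a=0.0,
                                  mus_prime=0.8, g=0.5)
        beam = BeamProfile(np.ones((20, 20)), 0.25, (0.125, 0.125))
        res = simulate_fluence(ph, beam, 750.0,
                               McConfig(n_photons=20_000, seed=4,
                                        domain_padding=0))
        assert res.energy_absorbed == 0.0
        assert res.energy_exited + res.roulette_residual == \
            pytest.approx(1.0, abs=1e-12)

    def test_energy_balance_closes(self):
        ph = uniform_slab_phantom((24, 24, 24), 0.25, mu_a=0.05,
                                  mus_prime=1.0, g=0.9)
        beam = BeamProfile(np.ones((24, 24)), 0.25, (0.125, 0.125))
        res = simulate_fluence(ph, beam, 750.0,
                               McConfig(n_photons=100_000, seed=5,
                                        domain_padding=0))
        assert res.energy_balance_error < 1e-3

    def test_absorbed_energy_consistent_with_fluence(self):
        """sum(mu_a Phi V_vox) equals the absorbed-energy tally."""
        mu_a = 0.08
        ph = uniform_slab_phantom((20, 20, 20), 0.25, mu_a=mu_a,
                                  mus_prime=1.0, g=0.9)
        beam = BeamProfile(np.ones((20, 20)), 0.25, (0.125, 0.125))
        res = simulate_fluence(ph, beam, 750.0,
                               McConfig(n_photons=20_000, seed=6,
                                        domain_padding=0))
        h_total = mu_a * res.fluence.values.sum() * ph.grid.voxel_volume
        assert h_total == pytest.approx(res.energy_absorbed, rel=1e-12)

    def test_diffusion_limit_agreement(self):
        """Deep fluence within 15% of the diffusion point-source oracle."""
        report = diffusion_check(n_photons=100_000, seed=2,
                                 depths_mm=(3.0, 4.0))
        assert report["max_rel_err"] < 0.15

    def test_seeded_runs_bit_identical(self):
        ph = uniform_slab_phantom((16, 16, 16), 0.25, mu_a=0.1,
                                  mus_prime=1.0, g=0.9)
        beam = BeamProfile(np.ones((16, 16)), 0.25, (0.125, 0.125))
        cfg = McConfig(n_photons=5000, seed=42, domain_padding=2)
        a = simulate_fluence(ph, beam, 750.0, cfg)
        b = simulate_fluence(ph, beam, 750.0, cfg)
        assert np.array_equal(a.fluence.values, b.fluence.values)

    def test_fluence_invariant_to_profile_amplitude(self):
        """Fluence is per unit incident energy: profile scaling cancels."""
        ph = uniform_slab_phantom((16, 16, 16), 0.25, mu_a=0.1,
                                  mus_prime=1.0, g=0.9)
        b1 = BeamProfile(np.ones((16, 16)), 0.25, (0.125, 0.125))
        b2 = BeamProfile(7.3 * np.ones((16, 16)), 0.25, (0.125, 0.125))
        cfg = McConfig(n_photons=3000, seed=9, domain_padding=0)
        a = simulate_fluence(ph, b1, 750.0, cfg)
        b = simulate_fluence(ph, b2, 750.0, cfg)
        assert np.array_equal(a.fluence.values, b.fluence.values)

    def test_wavelength_outside_table_rejected(self, rng):
        ph = uniform_slab_phantom((8, 8, 8), 0.25, 0.1, 1.0)
        beam = BeamProfile(np.ones((8, 8)), 0.25, (0.125, 0.125))
        with pytest.raises(ValueError, match="outside"):
            simulate_fluence(ph, beam, 1500.0,
                             McConfig(n_photons=10, domain_padding=0))
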