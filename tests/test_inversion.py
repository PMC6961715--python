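import numpy as np
import pytest

from qpat.calibration import CalibratedAbsorber
from qpat.experiments import beam_for, desk_phantom_config, synthesize_measured
from qpat.forward import forward_images
from qpat.grids import MultispectralImage, VoxelGrid
from qpat.inversion import (InversionConfig, InversionState, StepSizeConfig,
                            adam_update, chromophore_step_sizes,
                            error_functional, fluence_scaled_steps, gradient,
                            run_inversion)
from qpat.phantom import TubePhantomConfig, TubeSpec, make_tube_phantom
from qpat.spectra import ChromophoreSpectra
from qpat.validation import gradient_fd_check


def _stack(arrays, pitch=1.0):
    lams = [700.0 + 100.0 * i for i in range(len(arrays))]
    return MultispectralImage.from_arrays(lams, np.asarray(arrays), pitch)


class TestErrorFunctional:
    def test_zero_at_perfect_match(self, rng):
        m = rng.uniform(0.1, 1, (2, 4, 4, 4))
        k = 3.0
        assert error_functional(_stack(m), _stack(k * m), k) == 0.0

    def test_single_voxel_hand_case(self):
        # one voxel, one wavelength, V_vox = 1, K p0m - p0 = 2 -> 1/2*4 = 2
        measured = _stack(np.array([[[[3.0]]]]), pitch=1.0)
        model = _stack(np.array([[[[1.0]]]]), pitch=1.0)
        assert error_functional(measured, model, 1.0) == pytest.approx(2.0)

    def test_matches_bruteforce_voxel_loop(self, rng):
        m = rng.uniform(0, 1, (2, 3, 3, 3))
        p = rng.uniform(0, 1, (2, 3, 3, 3))
        k = 0.7
        pitch = 0.5
        acc = 0.0
        for li in range(2):
            for i in range(3):
                for j in range(3):
                    for kk in range(3):
                        acc += 0.5 * (k * m[li, i, j, kk]
                                      - p[li, i, j, kk]) ** 2 * pitch**3
        acc /= 2  # wavelength mean
        assert error_functional(_stack(m, pitch), _stack(p, pitch), k) == \
            pytest.approx(acc, rel=1e-12)


class TestGradient:
    def _spectra(self):
        return ChromophoreSpectra.from_table(
            names=["CuSO4", "NiSO4", "water"],
            wavelengths=[700.0, 800.0, 900.0],
            alpha=[[1.0, 1.5, 2.0], [2.0, 1.0, 0.5], [0.01, 0.02, 0.03]],
            beta=[0.708, 0.325, 0.0], c_max=[0.28, 1.54, 1.0])

    def test_zero_residual_gives_zero_gradient(self, rng):
        spectra = self._spectra()
        shape = (4, 4, 4)
        conc = {n: VoxelGrid(rng.uniform(0.1, 0.5, shape), 0.5)
                for n in spectra.names}
        fl = _stack(rng.uniform(0.1, 1, (3, *shape)), 0.5)
        fields = forward_images(conc, spectra, fl)
        k = 2.0
        measured = fields.p0.map(lambda v, _l: v / k)
        grads = gradient(measured, fields, fl, spectra, k)
        for g in grads.values():
            assert np.allclose(g, 0.0, atol=1e-15)

    def test_matches_frozen_fluence_finite_differences(self):
        """Analytic gradient within 1% of central differences."""
        report = gradient_fd_check(seed=3)
        assert report["max_rel_err"] < 0.01

    def test_insensitive_channel_has_zero_gradient(self, rng):
        spectra = ChromophoreSpectra.from_table(
            names=["dye", "inert"], wavelengths=[700.0, 800.0],
            alpha=[[1.0, 2.0], [0.0, 0.0]], beta=[0.5, 0.0],
            c_max=[1.0, 1.0])
        shape = (3, 3, 3)
        conc = {n: VoxelGrid(rng.uniform(0.1, 0.5, shape), 0.5)
                for n in spectra.names}
        fl = _stack(rng.uniform(0.1, 1, (2, *shape)), 0.5)
        fields = forward_images(conc, spectra, fl)
        measured = _stack(rng.uniform(0.1, 1, (2, *shape)), 0.5)
        grads = gradient(measured, fields, fl, spectra, 1.0)
        assert np.allclose(grads["inert"], 0.0)
        assert not np.allclose(grads["dye"], 0.0)


class TestStepSizes:
    def test_reference_chromophore_keeps_base_step(self, spectra,
                                                   wavelengths):
        gam = chromophore_step_sizes(spectra, wavelengths, gamma_cu=0.1)
        assert gam["CuSO4"] == pytest.approx(0.1)

    def test_clone_of_reference_gets_same_step(self):
        sp = ChromophoreSpectra.from_table(
            names=["CuSO4", "clone"], wavelengths=[700.0, 800.0],
            alpha=[[1.0, 2.0], [1.0, 2.0]], beta=[0.708, 0.708],
            c_max=[0.28, 0.28])
        gam = chromophore_step_sizes(sp, [700.0, 800.0], gamma_cu=0.1)
        assert gam["clone"] == pytest.approx(0.1)

    def test_fixture_step_matches_hand_formula(self, spectra, wavelengths):
        a = spectra.alpha(wavelengths)
        cu, ni = spectra.index("CuSO4"), spectra.index("NiSO4")
        expected = 0.1 * (a[cu].sum() * 0.28) / (a[ni].sum() * 1.54)
        gam = chromophore_step_sizes(spectra, wavelengths, gamma_cu=0.1)
        assert gam["NiSO4"] == pytest.approx(expected)

    def test_weak_absorber_gets_larger_step(self, spectra, wavelengths):
        gam = chromophore_step_sizes(spectra, wavelengths)
        assert gam["water"] > gam["CuSO4"]

    def test_zero_alpha_sum_rejected(self):
        sp = ChromophoreSpectra.from_table(
            names=["CuSO4", "dark"], wavelengths=[700.0],
            alpha=[[1.0], [0.0]], beta=[0.7, 0.0], c_max=[0.28, 1.0])
        with pytest.raises(ValueError, match="zero total"):
            chromophore_step_sizes(sp, [700.0])

    def test_fluence_scaling_extremes_and_monotonicity(self):
        shape = (2, 2, 2)
        phi = np.zeros((1, *shape))
        phi[0, 0, 0, 0] = 1.0   # Phi_norm = 1 at the peak voxel
        phi[0, 1, 1, 1] = 0.5
        fl = _stack(phi, 0.5)
        steps = fluence_scaled_steps({"c": 0.1}, fl, eps_phi=1e-4)["c"]
        assert steps[0, 0, 0] == pytest.approx(0.1 / (1 + 1e-4))
        assert steps[0, 0, 1] == pytest.approx(0.1 / 1e-4)  # Phi_norm = 0
        assert steps[1, 1, 1] == pytest.approx(0.1 / (0.5 + 1e-4))
        # monotone: smaller fluence -> larger step
        assert steps[0, 0, 1] > steps[1, 1, 1] > steps[0, 0, 0]

    def test_all_zero_fluence_rejected(self):
        fl = _stack(np.zeros((1, 2, 2, 2)), 0.5)
        with pytest.raises(ValueError, match="zero"):
            fluence_scaled_steps({"c": 0.1}, fl)


class TestAdamUpdate:
    def _state(self, shape=(2, 2, 2), value=0.5):
        s = InversionState.initial(["c"], shape)
        s.concentrations["c"][:] = value
        return s

    def test_zero_gradient_leaves_concentrations_unchanged(self):
        s = self._state()
        for _ in range(5):
            adam_update(s, {"c": np.zeros((2, 2, 2))},
                        {"c": 0.1}, {"c": 2.0})
        assert np.allclose(s.concentrations["c"], 0.5)

    def test_first_step_has_unit_magnitude_times_step(self):
        """Bias-corrected Adam: first update = step * sign(gradient)."""
        s = self._state(value=0.5)
        g = np.full((2, 2, 2), 3.7)
        adam_update(s, {"c": g}, {"c": 0.05}, {"c": 2.0},
                    StepSizeConfig())
        assert np.allclose(s.concentrations["c"], 0.5 - 0.05, atol=1e-6)

    def test_projection_onto_lower_bound(self):
        s = self._state(value=0.01)
        g = np.full((2, 2, 2), 1.0)
        adam_update(s, {"c": g}, {"c": 0.5}, {"c": 2.0})
        assert np.all(s.concentrations["c"] == 0.0)

    def test_projection_onto_upper_bound(self):
        s = self._state(value=1.95)
        g = np.full((2, 2, 2), -1.0)
        adam_update(s, {"c": g}, {"c": 0.5}, {"c": 2.0})
        assert np.all(s.concentrations["c"] == 2.0)

    def test_frozen_channel_untouched(self):
        s = InversionState.initial(["c", "water"], (2, 2, 2))
        adam_update(s, {"c": np.ones((2, 2, 2)),
                        "water": np.ones((2, 2, 2))},
                    {"c": 0.1, "water": 0.1}, {"c": 2.0, "water": 1.0},
                    frozen=("water",))
        assert np.all(s.concentrations["water"] == 1.0)


def _tiny_problem(seed=0, n_photons=4000):
    cfg = TubePhantomConfig(
        shape=(16, 8, 16), pitch=0.3, origin=(0.0, 0.0, 0.15),
        tubes=[TubeSpec(x=1.6, depth=1.2,
                        concentrations={"NiSO4": 0.77, "CuSO4": 0.14},
                        calibrated=True),
               TubeSpec(x=3.2, depth=2.8,
                        concentrations={"NiSO4": 0.385, "CuSO4": 0.21})])
    ph, _ = make_tube_phantom(cfg)
    beam = beam_for(cfg, padding=4)
    acq = synthesize_measured(ph, beam, (688.0, 765.0, 867.0),
                              n_photons=30_000, seed=seed + 50,
                              domain_padding=4, acoustic=False,
                              noise_snr_db=None)
    ca = CalibratedAbsorber.from_phantom(ph, 1, (688.0, 765.0, 867.0))
    return ph, beam, acq, ca


class TestRunInversion:
    def test_constraints_hold_and_run_is_reproducible(self):
        ph, beam, acq, ca = _tiny_problem()
        bounds = dict(zip(ph.spectra.names, ph.spectra.solubility_bounds))

        seen = []

        def check(it, state, eps):
            for name, c in state.concentrations.items():
                assert c.min() >= 0.0
                assert c.max() <= bounds[name] + 1e-12
            seen.append(eps)

        cfg = InversionConfig(n_iterations=3, n_photons=4000, seed=7,
                              domain_padding=4, checkpoint_every=2)
        res1 = run_inversion(acq.measured, ph, beam, ca, cfg, callback=check)
        assert len(seen) == 3
        assert all(np.isfinite(e) for e in seen)
        assert list(res1.checkpoints) == [1]
        assert set(res1.checkpoints[1]) == set(ph.spectra.names)
        res2 = run_inversion(acq.measured, ph, beam, ca, cfg)
        for name in ph.spectra.names:
            assert np.array_equal(res1.concentrations[name].values,
                                  res2.concentrations[name].values)

    def test_calibrated_absorber_voxels_stay_clamped(self):
        ph, beam, acq, ca = _tiny_problem()
        cfg = InversionConfig(n_iterations=2, n_photons=3000, seed=1,
                              domain_padding=4)
        res = run_inversion(acq.measured, ph, beam, ca, cfg)
        for name, value in ca.concentrations.items():
            assert np.allclose(res.concentrations[name].values[ca.mask],
                               value)

    def test_fixed_point_with_known_fluence(self):
        """Starting at the truth with the generating fluence: no motion.

        With the measured stack equal to the model output under the same
        (frozen) fluence, the residual, hence the gradient, vanishes and
        the estimate must not drift.
        """
        ph, beam, acq, ca = _tiny_problem()
        truth = {n: ph.concentrations[n].values.copy()
                 for n in ph.spectra.names}
        cfg = InversionConfig(n_iterations=5, n_photons=100, seed=2,
                              domain_padding=4)
        res = run_inversion(acq.measured, ph, beam, ca, cfg,
                            initial_concentrations=truth,
                            fixed_fluence=acq.fluence)
        for it in res.history:
            assert it["epsilon"] == pytest.approx(0.0, abs=1e-20)
        for name in ("NiSO4", "CuSO4"):
            assert np.allclose(res.concentrations[name].values,
                               truth[name], atol=1e-12)

    def test_error_decreases_from_water_start(self):
        ph, beam, acq, ca = _tiny_problem()
        cfg = InversionConfig(n_iterations=8, n_photons=5000, seed=3,
                              domain_padding=4)
        res = run_inversion(acq.measured, ph, beam, ca, cfg)
        eps = [h["epsilon"] for h in res.history]
        assert eps[-1] < eps[0]
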