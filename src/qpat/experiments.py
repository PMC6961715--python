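"""Ready-made in-silico experiments.

Two grid presets are provided.  The ``published`` preset records the full-scale
acquisition: 146 x 145 x 75 voxels at 110 um pitch, nine tubes at 2/4/7 mm
depth, 5e6 photon packets and 300 iterations.  The ``desk`` preset is the
same physics scaled to a single CPU core: a 32 x 32 x 28 grid at 250 um
pitch with two tubes (a shallow calibrated absorber and a deep target),
reduced photon and iteration budgets.  Both illuminate through the sensor
plane with the collimated near-Gaussian beam (1/e^2 diameter 13 mm) at the
five excitation wavelengths 688, 721, 765, 811 and 867 nm.

``synthesize_measured`` builds synthetic "measured" images: the optical
forward chain produces p0, which is then pushed through planar acoustic
detection and time reversal (so the limited-view correction has real work
to do) and polluted with white Gaussian noise at a set image SNR; an
inverse-crime mode skips acoustics and noise for controlled recovery
tests.  An arbitrary scanner-unit factor is applied so that the
calibrated-absorber scaling K is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acoustic import (AcousticConfig, planar_sensor_mask, propagate_forward,
                       time_reversal)
from .forward import forward_images
from .grids import MultispectralImage, VoxelGrid
from .mc import McConfig, simulate_fluence
from .phantom import (BeamProfile, Phantom, TubePhantomConfig, TubeSpec,
                      make_tube_phantom, reference_tube_layout)
from .spectra import ChromophoreSpectra, make_synthetic_spectra

__all__ = [
    "WAVELENGTHS_NM", "desk_phantom_config", "published_phantom_config",
    "beam_for", "simulate_fluence_stack", "add_image_noise",
    "SyntheticAcquisition", "synthesize_measured",
]

#: excitation wavelengths of the reference acquisition, nm
WAVELENGTHS_NM = (688.0, 721.0, 765.0, 811.0, 867.0)

#: arbitrary scanner-unit factor applied to synthetic measured images
SCANNER_UNIT_FACTOR = 250.0


def desk_phantom_config() -> TubePhantomConfig:
    """Two-tube desk-scale phantom: shallow calibrated absorber (2 mm,
    R = 50%) and a deep target tube (4 mm, R = 25%).

    The 9 x 9 mm aperture over the 4 mm tube keeps the aperture-to-depth
    ratio of the planar detection geometry (~2.3) equal to the reference
    acquisition's, so limited-view artifact levels are representative
    rather than artificially harsh.
    """
    tubes = [
        TubeSpec(x=3.2, depth=2.0,
                 concentrations={"NiSO4": 0.77, "CuSO4": 0.14},
                 calibrated=True),
        TubeSpec(x=5.8, depth=4.0,
                 concentrations={"NiSO4": 0.385, "CuSO4": 0.21}),
    ]
    return TubePhantomConfig(shape=(36, 36, 24), pitch=0.25,
                             origin=(0.0, 0.0, 0.125), tubes=tubes)


def published_phantom_config() -> TubePhantomConfig:
    """Nine-tube phantom on the published 146 x 145 x 75 grid (110 um)."""
    pitch = 0.11
    shape = (146, 145, 75)
    center = shape[0] * pitch / 2
    tubes = reference_tube_layout(center_x=center)
    return TubePhantomConfig(shape=shape, pitch=pitch,
                             origin=(0.0, 0.0, pitch / 2), tubes=tubes)


def beam_for(config: TubePhantomConfig, padding: int,
             d_1e2: float = 13.0) -> BeamProfile:
    """Gaussian beam sampled over the padded sensor face of a phantom."""
    nx, ny, _ = config.shape
    shape = (nx + 2 * padding, ny + 2 * padding)
    origin = (config.origin[0] - padding * config.pitch,
              config.origin[1] - padding * config.pitch)
    cx = config.origin[0] + (nx - 1) * config.pitch / 2
    cy = config.origin[1] + (ny - 1) * config.pitch / 2
    return BeamProfile.gaussian(shape, config.pitch, origin_xy=origin,
                                center=(cx, cy), d_1e2=d_1e2)


def simulate_fluence_stack(phantom: Phantom, beam: BeamProfile,
                           wavelengths, n_photons: int, seed: int,
                           domain_padding: int = 8) -> MultispectralImage:
    """MC fluence at every wavelength (one deterministic sub-seed each)."""
    vols = []
    for li, lam in enumerate(wavelengths):
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(li,))
        mc = McConfig(n_photons=n_photons,
                      seed=int(ss.generate_state(1, dtype=np.uint64)[0]),
                      domain_padding=domain_padding)
        vols.append(simulate_fluence(phantom, beam, lam, mc).fluence)
    return MultispectralImage(list(wavelengths), vols, quantity="fluence")


def add_image_noise(image: MultispectralImage, snr_db: float,
                    rng) -> MultispectralImage:
    """Additive white Gaussian noise at a given image SNR (dB).

    The noise standard deviation per wavelength is the RMS of that
    wavelength's volume divided by 10^(SNR/20).
    """
    vols = []
    for vol in image.volumes:
        rms = float(np.sqrt(np.mean(vol.values**2)))
        sigma = rms / 10.0 ** (snr_db / 20.0)
        vols.append(vol.like(vol.values + sigma * rng.standard_normal(vol.shape)))
    return MultispectralImage(list(image.wavelengths), vols,
                              quantity=image.quantity)


@dataclass
class SyntheticAcquisition:
    """Everything one in-silico acquisition produced."""

    phantom: Phantom
    beam: BeamProfile
    fluence: MultispectralImage       # generating fluence (high photon count)
    p0_true: MultispectralImage       # model-unit initial pressure
    measured: MultispectralImage      # scanner-unit images fed to inversion
    unit_factor: float


def synthesize_measured(phantom: Phantom, beam: BeamProfile,
                        wavelengths=WAVELENGTHS_NM, *,
                        n_photons: int = 200_000, seed: int = 0,
                        domain_padding: int = 8,
                        acoustic: bool = True,
                        acoustic_config: AcousticConfig | None = None,
                        noise_snr_db: float | None = 20.0,
                        unit_factor: float = SCANNER_UNIT_FACTOR,
                        ) -> SyntheticAcquisition:
    """Generate a synthetic measured image stack from a known phantom.

    With ``acoustic=True`` each p0 volume is propagated to the planar
    aperture and reconstructed by time reversal before noise is added —
    the realistic (non-inverse-crime) pipeline.  ``acoustic=False`` and
    ``noise_snr_db=None`` yield the inverse-crime stack (the optical
    forward output itself, in scanner units).
    """
    fluence = simulate_fluence_stack(phantom, beam, wavelengths, n_photons,
                                     seed, domain_padding)
    fields = forward_images(phantom.concentrations, phantom.spectra, fluence,
                            phantom.gamma_water)
    p0_true = fields.p0

    if acoustic:
        cfg = acoustic_config or AcousticConfig(pml_size=8)
        mask = planar_sensor_mask(p0_true.grid.shape)
        vols = []
        for lam, vol in zip(p0_true.wavelengths, p0_true.volumes):
            series = propagate_forward(vol, cfg, mask)
            vols.append(time_reversal(series, cfg))
        measured = MultispectralImage(list(p0_true.wavelengths), vols,
                                      quantity="p0")
    else:
        measured = p0_true

    if noise_snr_db is not None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(999,)))
        measured = add_image_noise(measured, noise_snr_db, rng)

    measured = measured.map(lambda v, _lam: unit_factor * v)
    return SyntheticAcquisition(phantom=phantom, beam=beam, fluence=fluence,
                                p0_true=p0_true, measured=measured,
                                unit_factor=unit_factor)
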