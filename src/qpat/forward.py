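"""Optical-to-acoustic forward map: concentrations + fluence -> p0.

The initial pressure is p0(r, lambda) = Gamma(r) H(r, lambda) with
H = mu_a * Phi.  Absorption mixes linearly over chromophores,
mu_a = sum_k c_k(r) alpha_k(lambda), and the Gruneisen parameter carries a
linear concentration dependence Gamma = Gamma_water (1 + sum_k beta_k c_k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import MultispectralImage, VoxelGrid
from .spectra import ChromophoreSpectra

__all__ = ["absorption_map", "grueneisen_map", "initial_pressure",
           "ForwardResult", "forward_images"]


def _conc_stack(concentrations: dict[str, VoxelGrid],
                spectra: ChromophoreSpectra) -> tuple[np.ndarray, VoxelGrid]:
    missing = set(spectra.names) - set(concentrations)
    if missing:
        raise KeyError(f"missing concentration channels: {sorted(missing)}")
    ref = concentrations[spectra.names[0]]
    arr = np.stack([concentrations[n].values for n in spectra.names])
    if np.any(arr < 0):
        raise ValueError("concentrations must be non-negative")
    return arr, ref


def absorption_map(concentrations: dict[str, VoxelGrid],
                   spectra: ChromophoreSpectra,
                   wavelength: float) -> VoxelGrid:
    """mu_a(r) = sum_k c_k(r) alpha_k(lambda), mm^-1."""
    arr, ref = _conc_stack(concentrations, spectra)
    alpha = spectra.alpha(wavelength)  # (n_k,)
    mu_a = np.tensordot(alpha, arr, axes=(0, 0))
    return ref.like(mu_a)


def grueneisen_map(concentrations: dict[str, VoxelGrid],
                   spectra: ChromophoreSpectra,
                   gamma_water: float = 0.124) -> VoxelGrid:
    """Gamma(r) = Gamma_water * (1 + sum_k beta_k c_k(r)), dimensionless."""
    arr, ref = _conc_stack(concentrations, spectra)
    gamma = gamma_water * (1.0 + np.tensordot(spectra.beta, arr, axes=(0, 0)))
    return ref.like(gamma)


def initial_pressure(mu_a: VoxelGrid, gamma: VoxelGrid,
                     fluence: VoxelGrid) -> VoxelGrid:
    """p0 = Gamma * H = Gamma * mu_a * Phi, voxelwise."""
    for other in (gamma, fluence):
        if not mu_a.same_geometry(other):
            raise ValueError("mu_a, gamma and fluence must share geometry")
    return mu_a.like(gamma.values * mu_a.values * fluence.values)


@dataclass
class ForwardResult:
    """Per-wavelength fields of one forward evaluation (model units)."""

    mu_a: MultispectralImage          # mm^-1
    gamma: VoxelGrid                  # dimensionless
    H: MultispectralImage             # J mm^-3 per J incident
    p0: MultispectralImage            # Gamma * H


def forward_images(concentrations: dict[str, VoxelGrid],
                   spectra: ChromophoreSpectra,
                   fluence: MultispectralImage,
                   gamma_water: float = 0.124) -> ForwardResult:
    """Evaluate the full optical forward chain for a fluence stack."""
    gamma = grueneisen_map(concentrations, spectra, gamma_water)
    mu_a_vols, h_vols, p0_vols = [], [], []
    for lam, phi in zip(fluence.wavelengths, fluence.volumes):
        mu_a = absorption_map(concentrations, spectra, lam)
        h = mu_a.like(mu_a.values * phi.values)
        mu_a_vols.append(mu_a)
        h_vols.append(h)
        p0_vols.append(h.like(gamma.values * h.values))
    lam = list(fluence.wavelengths)
    return ForwardResult(
        mu_a=MultispectralImage(lam, mu_a_vols, quantity="absorbed_energy"),
        gamma=gamma,
        H=MultispectralImage(lam, h_vols, quantity="absorbed_energy"),
        p0=MultispectralImage(lam, p0_vols, quantity="p0"),
    )
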