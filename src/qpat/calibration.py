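"""Calibrated-absorber scaling of measured images to model units.

Measured photoacoustic image intensities are in arbitrary scanner units.
An absorber of known mu_a(lambda) and Gruneisen parameter inside the image
volume ties them to the forward model: the scaling factor K is the mean of
Gamma * H0 / p0m over the absorber sub-volume and all wavelengths, so
K = 1 when measured and model agree and K is independent of the mask size
and of the number of wavelengths (a pure scale factor, as its
multiplicative use in the error functional requires).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import MultispectralImage

__all__ = ["CalibratedAbsorber", "scaling_factor",
           "refine_mask_by_intensity"]


def refine_mask_by_intensity(mask: np.ndarray, measured,
                             keep_frac: float = 0.5) -> np.ndarray:
    """Keep the brightest core of a calibrated-absorber segment.

    Mimics the conservative manual segmentation applied to measured data:
    of the masked voxels, only those whose worst-case (minimum over
    wavelengths) measured intensity is positive and within the top
    ``keep_frac`` are retained, discarding edge voxels corrupted by
    partial-volume and reconstruction ringing.
    """
    if not 0 < keep_frac <= 1:
        raise ValueError("keep_frac must be in (0, 1]")
    stack = measured.as_array()
    worst = stack.min(axis=0)
    vals = worst[mask]
    cutoff = np.quantile(vals, 1.0 - keep_frac)
    refined = mask & (worst >= max(cutoff, 0.0)) & (worst > 0)
    if not refined.any():
        raise ValueError("no positive-intensity voxels left in the "
                         "calibrated-absorber mask")
    return refined


@dataclass
class CalibratedAbsorber:
    """Known reference absorber inside the image volume.

    ``mask`` is a boolean volume on the image grid; ``mu_a`` maps
    wavelength (nm) to the known absorption coefficient (mm^-1);
    ``gamma`` is the known Gruneisen parameter.  ``concentrations``
    optionally records the known chromophore fill (used by the inversion
    to hold the absorber's mu_a and Gamma fixed).
    """

    mask: np.ndarray
    mu_a: dict[float, float]
    gamma: float
    concentrations: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("calibrated-absorber mask is empty")
        self.mu_a = {float(k): float(v) for k, v in self.mu_a.items()}

    def mu_a_at(self, wavelength: float) -> float:
        try:
            return self.mu_a[float(wavelength)]
        except KeyError:
            raise KeyError(f"calibrated absorber has no mu_a tabulated at "
                           f"{wavelength} nm") from None

    @classmethod
    def from_phantom(cls, phantom, label: int, wavelengths,
                     erode: int = 0) -> "CalibratedAbsorber":
        """Build the reference from a labelled tube of a known phantom.

        ``erode`` shrinks the mask by that many voxels, mimicking the
        conservative manual segmentation used on measured data (edge
        voxels suffer partial-volume and reconstruction-ringing effects).
        """
        mask = phantom.labels.values.astype(np.int64) == int(label)
        if erode > 0:
            from scipy.ndimage import binary_erosion
            eroded = binary_erosion(mask, iterations=erode)
            if eroded.any():
                mask = eroded
        if not mask.any():
            raise ValueError(f"phantom has no voxels with label {label}")
        spectra = phantom.spectra
        conc = {}
        for name in spectra.names:
            vals = np.unique(phantom.concentrations[name].values[mask])
            if vals.size != 1:
                raise ValueError(f"label {label} is not homogeneous in "
                                 f"channel {name!r}")
            conc[name] = float(vals[0])
        c_vec = np.array([conc[n] for n in spectra.names])
        mu_a = {float(lam): float(np.dot(spectra.alpha(float(lam)), c_vec))
                for lam in wavelengths}
        gamma = phantom.gamma_water * (1.0 + float(np.dot(spectra.beta, c_vec)))
        return cls(mask=mask, mu_a=mu_a, gamma=gamma, concentrations=conc)


def scaling_factor(measured: MultispectralImage, model_h: MultispectralImage,
                   ca: CalibratedAbsorber) -> float:
    """Scaling factor K = mean over (mask, lambda) of Gamma H0 / p0m.

    ``model_h`` is the absorbed energy density predicted with the current
    fluence and the calibrated absorber's fixed mu_a; ``measured`` must be
    strictly positive on the mask (guaranteed after thresholding).
    """
    if measured.wavelengths != model_h.wavelengths:
        raise ValueError("measured and model stacks must share wavelengths")
    if ca.mask.shape != measured.grid.shape:
        raise ValueError("calibrated-absorber mask must be on the image grid")
    ratios = []
    for lam in measured.wavelengths:
        m = measured[lam].values[ca.mask]
        h = model_h[lam].values[ca.mask]
        if np.any(m <= 0):
            raise ValueError(f"measured image is not positive on the "
                             f"calibrated-absorber mask at {lam} nm")
        ratios.append(ca.gamma * h / m)
    k = float(np.mean(ratios))
    if not k > 0:
        raise ValueError(f"non-positive scaling factor K={k}")
    return k
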