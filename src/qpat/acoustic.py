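"""Acoustic propagation, time-reversal reconstruction and limited-view
correction.

The wave solver is a first-order (pressure-velocity) k-space pseudospectral
scheme on a homogeneous medium: spectral derivatives on a spatially
staggered grid, the k-space correction factor kappa = sinc(c0 |k| dt / 2)
that renders the homogeneous scheme dispersion-exact, and a split-field
perfectly matched layer (PML) wrapped around the image volume.  A planar
detection aperture under-samples the acoustic field; the resulting
intensity loss is estimated by pushing the (smoothed, thresholded) measured
images through a forward-propagate / time-reverse round trip over the same
aperture and dividing, yielding a wavelength-averaged correction matrix
eta(r) with which the measured images are rescaled.  Using a single eta at
all wavelengths preserves the spectral shape of the data voxel by voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from .grids import MultispectralImage, VoxelGrid

__all__ = [
    "AcousticConfig", "SensorSeries", "CorrectionMatrix",
    "planar_sensor_mask", "closed_surface_mask",
    "propagate_forward", "time_reversal",
    "smooth_and_threshold", "limited_view_correction",
]


@dataclass
class AcousticConfig:
    """Solver settings.

    ``c0`` in m/s (default: the phantom's measured sound speed), CFL
    number dt * c0 / dx (must be <= 0.3 for the schemes used here), PML
    thickness in voxels and absorption exponent profile strength.
    ``duration_factor`` sets the simulated time as a multiple of one
    domain traversal of the computational grid.
    """

    c0: float = 1499.0
    rho0: float = 1000.0
    cfl: float = 0.3
    pml_size: int = 10
    pml_alpha: float = 2.0
    duration_factor: float = 2.0
    threshold_frac: float = 0.01
    eta_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.cfl <= 0 or self.cfl > 0.3:
            raise ValueError(f"CFL number must be in (0, 0.3], got {self.cfl}")
        if self.pml_size < 0:
            raise ValueError("pml_size must be >= 0")


@dataclass
class SensorSeries:
    """Time-resolved pressure at the detector voxels.

    ``pressure`` has shape ``(n_detectors, n_t)`` where detectors are the
    ``True`` voxels of ``sensor_mask`` (an image-grid boolean volume) in
    C order.  The grid geometry is carried along so a reconstruction can
    validate compatibility.
    """

    pressure: np.ndarray
    dt: float
    c0: float
    sensor_mask: np.ndarray
    grid_shape: tuple[int, int, int]
    pitch: float
    origin: tuple[float, float, float]

    @property
    def n_t(self) -> int:
        return self.pressure.shape[1]


@dataclass
class CorrectionMatrix:
    """Limited-view correction matrix eta(r), dimensionless, > 0."""

    eta: VoxelGrid


def planar_sensor_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Detectors on the z = 0 face (planar scanner aperture)."""
    mask = np.zeros(shape, dtype=bool)
    mask[:, :, 0] = True
    return mask


def closed_surface_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Detectors on all six faces (full-aperture reference)."""
    mask = np.zeros(shape, dtype=bool)
    mask[0, :, :] = mask[-1, :, :] = True
    mask[:, 0, :] = mask[:, -1, :] = True
    mask[:, :, 0] = mask[:, :, -1] = True
    return mask


# ----------------------------------------------------------------------
# k-space solver
# ----------------------------------------------------------------------

class _KSpaceSolver:
    """First-order k-space pseudospectral solver on the padded grid."""

    def __init__(self, image_shape: tuple[int, int, int], pitch_mm: float,
                 config: AcousticConfig):
        self.config = config
        self.pml = config.pml_size
        self.image_shape = tuple(image_shape)
        # round up to FFT-friendly sizes; the slack sits inside the
        # absorbing boundary and never touches the image volume
        self.shape = tuple(sp_fft.next_fast_len(s + 2 * self.pml, real=True)
                           for s in image_shape)
        self.dx = pitch_mm * 1e-3            # m
        self.c0 = config.c0
        self.rho0 = config.rho0
        self.dt = config.cfl * self.dx / self.c0

        nx, ny, nz = self.shape
        kx = 2 * np.pi * sp_fft.fftfreq(nx, self.dx)
        ky = 2 * np.pi * sp_fft.fftfreq(ny, self.dx)
        # real-input transform along the last axis: all spectral operators
        # here are conjugate-symmetric, so the fields stay real
        kz = 2 * np.pi * sp_fft.rfftfreq(nz, self.dx)
        kmag = np.sqrt(kx[:, None, None] ** 2 + ky[None, :, None] ** 2
                       + kz[None, None, :] ** 2)
        # kappa = sinc(c0 |k| dt / 2) makes the homogeneous scheme exact
        self.kappa = np.sinc(self.c0 * kmag * self.dt / (2 * np.pi))
        half = self.dx / 2
        self.op_pos = [  # derivative onto the staggered (+dx/2) grid
            (1j * kx * np.exp(1j * kx * half))[:, None, None],
            (1j * ky * np.exp(1j * ky * half))[None, :, None],
            (1j * kz * np.exp(1j * kz * half))[None, None, :],
        ]
        self.op_neg = [  # staggered grid back to the regular grid
            (1j * kx * np.exp(-1j * kx * half))[:, None, None],
            (1j * ky * np.exp(-1j * ky * half))[None, :, None],
            (1j * kz * np.exp(-1j * kz * half))[None, None, :],
        ]
        self.pml_reg, self.pml_sg = self._pml_factors()

    def _pml_profile(self, n: int, staggered: bool) -> np.ndarray:
        """exp(-sigma dt / 2) absorption factor along one axis."""
        pml = self.pml
        idx = np.arange(n) + (0.5 if staggered else 0.0)
        sigma = np.zeros(n)
        if pml > 0 and self.config.pml_alpha > 0:
            d_left = (pml - idx) / pml
            d_right = (idx - (n - 1 - pml)) / pml
            depth = np.maximum(0.0, np.maximum(d_left, d_right))
            sigma = self.config.pml_alpha * (self.c0 / self.dx) * depth**4
        return np.exp(-sigma * self.dt / 2)

    def _pml_factors(self):
        reg, sg = [], []
        for ax, n in enumerate(self.shape):
            shape = [1, 1, 1]
            shape[ax] = n
            reg.append(self._pml_profile(n, False).reshape(shape))
            sg.append(self._pml_profile(n, True).reshape(shape))
        return reg, sg

    # -- helpers --------------------------------------------------------
    def n_steps(self) -> int:
        t_end = self.config.duration_factor * max(self.shape) * self.dx / self.c0
        return int(np.ceil(t_end / self.dt))

    def embed(self, image_values: np.ndarray) -> np.ndarray:
        out = np.zeros(self.shape)
        p = self.pml
        nx, ny, nz = self.image_shape
        out[p:p + nx, p:p + ny, p:p + nz] = image_values
        return out

    def crop(self, values: np.ndarray) -> np.ndarray:
        p = self.pml
        nx, ny, nz = self.image_shape
        return values[p:p + nx, p:p + ny, p:p + nz].copy()

    def _grad_stag(self, p: np.ndarray) -> list[np.ndarray]:
        pk = self.kappa * sp_fft.rfftn(p)
        return [sp_fft.irfftn(op * pk, s=self.shape) for op in self.op_pos]

    def _div_comp(self, u: np.ndarray, axis: int) -> np.ndarray:
        return sp_fft.irfftn(self.op_neg[axis] * self.kappa * sp_fft.rfftn(u),
                             s=self.shape)

    # -- time stepping --------------------------------------------------
    def run_forward(self, p0_padded: np.ndarray, sensor_full: np.ndarray,
                    n_steps: int) -> np.ndarray:
        """March ``n_steps`` and record p at ``sensor_full`` voxels.

        Returns ``(n_detectors, n_steps)``; sample 0 is the initial state.
        """
        c2 = self.c0**2
        rho = [p0_padded / (3 * c2) for _ in range(3)]
        p = p0_padded.copy()
        grad = self._grad_stag(p)
        u = [-(self.dt / (2 * self.rho0)) * g for g in grad]  # half-step IC
        det = np.where(sensor_full.ravel())[0]
        rec = np.empty((det.size, n_steps))
        rec[:, 0] = p.ravel()[det]
        for n in range(1, n_steps):
            grad = self._grad_stag(p)
            for ax in range(3):
                u[ax] = self.pml_sg[ax] * (self.pml_sg[ax] * u[ax]
                                           - (self.dt / self.rho0) * grad[ax])
            for ax in range(3):
                div = self._div_comp(u[ax], ax)
                rho[ax] = self.pml_reg[ax] * (self.pml_reg[ax] * rho[ax]
                                              - self.dt * self.rho0 * div)
            p = c2 * (rho[0] + rho[1] + rho[2])
            rec[:, n] = p.ravel()[det]
        return rec

    def run_reversal(self, series: np.ndarray, sensor_full: np.ndarray
                     ) -> np.ndarray:
        """Re-emit the time-reversed series as a Dirichlet source.

        The recorded pressures are enforced at the sensor voxels in
        reverse temporal order; the final pressure field approximates p0.
        """
        c2 = self.c0**2
        det = np.where(sensor_full.ravel())[0]
        p = np.zeros(self.shape)
        rho = [np.zeros(self.shape) for _ in range(3)]
        u = [np.zeros(self.shape) for _ in range(3)]
        n_t = series.shape[1]

        def enforce(values):
            flat = p.reshape(-1)
            flat[det] = values
            for ax in range(3):
                rho[ax].reshape(-1)[det] = values / (3 * c2)

        enforce(series[:, n_t - 1])
        for n in range(n_t - 2, -1, -1):
            grad = self._grad_stag(p)
            for ax in range(3):
                u[ax] = self.pml_sg[ax] * (self.pml_sg[ax] * u[ax]
                                           - (self.dt / self.rho0) * grad[ax])
            for ax in range(3):
                div = self._div_comp(u[ax], ax)
                rho[ax] = self.pml_reg[ax] * (self.pml_reg[ax] * rho[ax]
                                              - self.dt * self.rho0 * div)
            p = c2 * (rho[0] + rho[1] + rho[2])
            enforce(series[:, n])
        return p


# ----------------------------------------------------------------------
# Public operations
# ----------------------------------------------------------------------

def propagate_forward(p0: VoxelGrid, config: AcousticConfig,
                      sensor_mask: np.ndarray | None = None,
                      n_steps: int | None = None) -> SensorSeries:
    """Propagate an initial pressure to the detector voxels.

    ``sensor_mask`` is a boolean volume on the image grid (default: the
    planar z = 0 aperture).  The simulated duration covers two traversals
    of the computational domain unless ``n_steps`` is given.
    """
    if sensor_mask is None:
        sensor_mask = planar_sensor_mask(p0.shape)
    if sensor_mask.shape != p0.shape:
        raise ValueError("sensor mask shape must match the image grid")
    solver = _KSpaceSolver(p0.shape, p0.pitch, config)
    steps = n_steps if n_steps is not None else solver.n_steps()
    sensor_full = solver.embed(sensor_mask.astype(float)) > 0.5
    rec = solver.run_forward(solver.embed(p0.values), sensor_full, steps)
    return SensorSeries(pressure=rec, dt=solver.dt, c0=config.c0,
                        sensor_mask=sensor_mask.copy(), grid_shape=p0.shape,
                        pitch=p0.pitch, origin=p0.origin)


def time_reversal(series: SensorSeries, config: AcousticConfig,
                  grid: VoxelGrid | None = None) -> VoxelGrid:
    """Reconstruct p0 by time-reversing a recorded series.

    Positivity is deliberately not enforced: limited-view artifacts
    (including negative excursions) are part of what downstream stages
    must cope with.
    """
    if grid is not None:
        if (grid.shape != series.grid_shape
                or not np.isclose(grid.pitch, series.pitch)):
            raise ValueError("target grid is incompatible with the series")
        origin = grid.origin
    else:
        origin = series.origin
    if abs(config.c0 - series.c0) > 1e-9:
        raise ValueError("config sound speed differs from the series")
    solver = _KSpaceSolver(series.grid_shape, series.pitch, config)
    if abs(solver.dt - series.dt) / series.dt > 1e-9:
        raise ValueError("series time step incompatible with solver settings")
    sensor_full = solver.embed(series.sensor_mask.astype(float)) > 0.5
    p_final = solver.run_reversal(series.pressure, sensor_full)
    return VoxelGrid(values=solver.crop(p_final), pitch=series.pitch,
                     origin=origin)


def _hann_kspace_window(shape: tuple[int, int, int]) -> np.ndarray:
    win = np.ones(())
    parts = []
    for n in shape:
        f = sp_fft.fftfreq(n)
        parts.append(0.5 * (1.0 + np.cos(2 * np.pi * f)))
    wx, wy, wz = parts
    return wx[:, None, None] * wy[None, :, None] * wz[None, None, :]


def smooth_and_threshold(image: MultispectralImage,
                         threshold_frac: float = 0.01) -> MultispectralImage:
    """Hann-window k-space smoothing, then a relative noise floor.

    Each wavelength's volume is low-pass filtered with a separable Hann
    window in the spatial-frequency domain (unit DC gain, so the volume
    sum is preserved) and values below ``threshold_frac`` of that
    wavelength's maximum are raised to the threshold, guarding later
    divisions.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    window = _hann_kspace_window(image.grid.shape)

    def _one(values, _lam):
        smoothed = sp_fft.ifftn(sp_fft.fftn(values) * window).real
        peak = smoothed.max()
        if peak <= 0:
            raise ValueError("cannot threshold a non-positive volume "
                             "(all-zero input?)")
        return np.maximum(smoothed, threshold_frac * peak)

    return image.map(_one)


def limited_view_correction(measured: MultispectralImage,
                            config: AcousticConfig,
                            sensor_mask: np.ndarray | None = None,
                            ) -> tuple[CorrectionMatrix, MultispectralImage]:
    """Estimate and undo the intensity loss of limited-view detection.

    Per wavelength the smoothed/thresholded measured image is forward
    propagated to the detection aperture and time reversed; the ratio of
    round-trip to input, averaged over wavelengths, is the correction
    matrix eta(r).  The measured images divided by eta are returned
    alongside eta.  Because one eta is shared by all wavelengths, the
    voxelwise spectral ratios of the data are unchanged.
    """
    grid = measured.grid
    if sensor_mask is None:
        sensor_mask = planar_sensor_mask(grid.shape)
    smoothed = smooth_and_threshold(measured, config.threshold_frac)
    eta_acc = np.zeros(grid.shape)
    for lam, vol in zip(smoothed.wavelengths, smoothed.volumes):
        series = propagate_forward(vol, config, sensor_mask)
        roundtrip = time_reversal(series, config)
        eta_acc += roundtrip.values / vol.values
    eta = eta_acc / len(smoothed)
    if np.any(~np.isfinite(eta)):
        raise FloatingPointError("limited-view correction produced "
                                 "non-finite eta values")
    eta = np.maximum(eta, config.eta_floor)
    corrected = measured.map(lambda v, _lam: v / eta)
    if any(np.any(~np.isfinite(v.values)) for v in corrected.volumes):
        raise FloatingPointError("corrected images contain non-finite values")
    return CorrectionMatrix(eta=grid.like(eta)), corrected
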