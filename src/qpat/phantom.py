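"""Digital tissue phantoms: tube geometry, scattering law and beam profile.

The reference phantom emulates a planar-scanner test object: nine parallel
polymer tubes (inner diameter 670 um) suspended at roughly 2, 4 and 7 mm
depth in a scattering background of diluted milk, filled with CuSO4/NiSO4
mixtures, and illuminated through the sensor plane by a collimated beam
with a near-Gaussian profile (1/e^2 diameter ~ 13 mm).  Tube walls are not
modelled optically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grids import VoxelGrid
from .spectra import ChromophoreSpectra, make_synthetic_spectra

__all__ = [
    "mus_prime", "mus_from_mus_prime", "BeamProfile", "TubeSpec",
    "TubePhantomConfig", "Phantom", "make_tube_phantom",
    "reference_tube_layout",
]

#: milk-dilution reduced-scattering fit mus'(lambda) = a * (lambda/nm)^b, mm^-1
MILK_MUS_PRIME_PARAMS = (6.65e3, -1.317)
GAMMA_WATER = 0.124
N_WATER = 1.33
N_SENSOR = 1.5


def mus_prime(lambda_nm, a: float = MILK_MUS_PRIME_PARAMS[0],
              b: float = MILK_MUS_PRIME_PARAMS[1]):
    """Reduced scattering coefficient mus'(lambda) = a * (lambda/nm)^b, mm^-1.

    The empirical power law interpolates time-resolved transmittance
    measurements of the diluted-milk background (a = 6.65e3, b = -1.317
    gives ~1 mm^-1 at 800 nm).  Raises if the parameters produce a
    non-positive coefficient at any requested wavelength.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    out = a * lam**b
    if np.any(out <= 0):
        raise ValueError(f"mus'={out} <= 0 for a={a}, b={b}: unphysical fit")
    return float(out) if np.isscalar(lambda_nm) else out


def mus_from_mus_prime(msp, g: float):
    """Scattering coefficient mus = mus' / (1 - g) by similarity relation."""
    if not 0 <= g < 1:
        raise ValueError(f"anisotropy g must be in [0, 1), got {g}")
    return msp / (1.0 - g)


# ----------------------------------------------------------------------
@dataclass
class BeamProfile:
    """Irradiance map of the excitation beam over the sensor (z=0) plane.

    ``profile`` is normalized so that its integral over the plane equals a
    unit pulse energy: ``profile.sum() * pitch**2 == 1``.
    """

    profile: np.ndarray
    pitch: float
    origin_xy: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)
    d_1e2: float | None = None

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=np.float64)
        if self.profile.ndim != 2:
            raise ValueError("beam profile must be 2-D")
        if np.any(self.profile < 0):
            raise ValueError("beam profile must be non-negative")
        total = self.profile.sum() * self.pitch**2
        if total <= 0:
            raise ValueError("beam profile has zero total energy")
        if not np.isclose(total, 1.0, rtol=1e-9):
            self.profile = self.profile / total

    @property
    def total_energy(self) -> float:
        return float(self.profile.sum() * self.pitch**2)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.profile.shape
        x = self.origin_xy[0] + self.pitch * np.arange(nx)
        y = self.origin_xy[1] + self.pitch * np.arange(ny)
        return x, y

    @classmethod
    def gaussian(cls, shape: tuple[int, int], pitch: float,
                 origin_xy: tuple[float, float] = (0.0, 0.0),
                 center: tuple[float, float] | None = None,
                 d_1e2: float = 13.0) -> "BeamProfile":
        """Collimated Gaussian beam; ``d_1e2`` is the 1/e^2 diameter in mm."""
        nx, ny = shape
        x = origin_xy[0] + pitch * np.arange(nx)
        y = origin_xy[1] + pitch * np.arange(ny)
        if center is None:
            center = (float(x.mean()), float(y.mean()))
        w = d_1e2 / 2.0  # 1/e^2 radius
        xx, yy = np.meshgrid(x - center[0], y - center[1], indexing="ij")
        prof = np.exp(-2.0 * (xx**2 + yy**2) / w**2)
        return cls(profile=prof, pitch=pitch, origin_xy=origin_xy,
                   center=center, d_1e2=d_1e2)

    @classmethod
    def delta(cls, position: tuple[float, float], pitch: float,
              shape: tuple[int, int] = (1, 1)) -> "BeamProfile":
        """Pencil beam: all energy in a single pixel at ``position``."""
        prof = np.zeros(shape)
        prof[0, 0] = 1.0
        return cls(profile=prof, pitch=pitch, origin_xy=position,
                   center=position, d_1e2=0.0)


# ----------------------------------------------------------------------
@dataclass
class TubeSpec:
    """A straight tube parallel to the y axis.

    ``concentrations`` maps chromophore name to fill concentration (M for
    solutes; the water volume fraction defaults to 1 if not given).
    """

    x: float                      # lateral centre, mm
    depth: float                  # axis depth below the sensor plane, mm
    concentrations: dict[str, float] = field(default_factory=dict)
    inner_radius: float = 0.335   # mm (inner diameter 670 um)
    calibrated: bool = False


@dataclass
class TubePhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 48)
    pitch: float = 0.15                      # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tubes: list[TubeSpec] = field(default_factory=list)
    mus_prime_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"background": MILK_MUS_PRIME_PARAMS,
                                 "tubes": MILK_MUS_PRIME_PARAMS})
    g: float = 0.9
    n_internal: float = N_WATER
    n_external: float = N_SENSOR
    gamma_water: float = GAMMA_WATER


@dataclass
class Phantom:
    """Known ground truth: concentration maps plus fixed optical properties."""

    concentrations: dict[str, VoxelGrid]
    spectra: ChromophoreSpectra
    labels: VoxelGrid
    mus_prime_params: dict[str, tuple[float, float]]
    g: float = 0.9
    n_internal: float = N_WATER
    n_external: float = N_SENSOR
    gamma_water: float = GAMMA_WATER
    calibrated_label: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.g < 1:
            raise ValueError("anisotropy g must be in [0, 1)")
        for name, vol in self.concentrations.items():
            if np.any(vol.values < 0):
                raise ValueError(f"negative concentration in channel {name!r}")
        if "water" in self.concentrations:
            w = self.concentrations["water"].values
            if np.any(w > 1.0 + 1e-12):
                raise ValueError("water volume fraction must be within [0, 1]")

    @property
    def grid(self) -> VoxelGrid:
        return next(iter(self.concentrations.values()))

    def concentration_array(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = list(names or self.spectra.names)
        return np.stack([self.concentrations[n].values for n in names])

    def mus_volume(self, wavelength_nm: float) -> np.ndarray:
        """Scattering coefficient mus (mm^-1) per voxel at one wavelength."""
        a_bg, b_bg = self.mus_prime_params["background"]
        msp = np.full(self.grid.shape,
                      mus_prime(wavelength_nm, a_bg, b_bg), dtype=np.float64)
        if "tubes" in self.mus_prime_params:
            a_t, b_t = self.mus_prime_params["tubes"]
            msp[self.labels.values > 0] = mus_prime(wavelength_nm, a_t, b_t)
        return mus_from_mus_prime(msp, self.g)


def reference_tube_layout(spectra_names: Sequence[str] = ("CuSO4", "NiSO4", "water"),
                      lateral_positions: Sequence[float] = (-4.0, 0.0, 4.0),
                      depths: Sequence[float] = (2.0, 4.0, 7.0),
                      center_x: float = 0.0) -> list[TubeSpec]:
    """Nine-tube layout: three rows of three tubes at ~2/4/7 mm depth.

    Fill mixtures follow the reference phantom's true concentrations
    (tube IDs 1..9 row-major, shallow row first); tube 2 — the shallow
    centre tube — is the calibrated absorber.
    """
    fills = [  # (c_NiSO4 [M], c_CuSO4 [M])
        (0.385, 0.21), (0.77, 0.14), (1.154, 0.07),   # 2 mm row
        (1.154, 0.07), (0.0, 0.28), (0.385, 0.21),    # 4 mm row
        (1.539, 0.0), (0.77, 0.14), (0.0, 0.28),      # 7 mm row
    ]
    tubes = []
    tid = 0
    for depth in depths:
        for x in lateral_positions:
            c_ni, c_cu = fills[tid]
            conc = {}
            if "NiSO4" in spectra_names:
                conc["NiSO4"] = c_ni
            if "CuSO4" in spectra_names:
                conc["CuSO4"] = c_cu
            tubes.append(TubeSpec(x=center_x + x, depth=depth,
                                  concentrations=conc,
                                  calibrated=(tid == 1)))
            tid += 1
    return tubes


def make_tube_phantom(config: TubePhantomConfig,
                      spectra: ChromophoreSpectra | None = None,
                      ) -> tuple[Phantom, VoxelGrid]:
    """Paint tube mixtures into a water background.

    Returns the :class:`Phantom` and an integer label volume (0 =
    background, 1..N = tube ID in the order of ``config.tubes``).  Tube
    interiors are cylinders of voxels whose centres lie inside the
    analytic inner radius; walls are treated as background.  A tube
    extending beyond the grid, or overlapping another tube, is an error.
    """
    if spectra is None:
        spectra = make_synthetic_spectra()
    shape, pitch, origin = config.shape, config.pitch, config.origin
    if not config.tubes:
        raise ValueError("phantom config lists no tubes")

    x = origin[0] + pitch * np.arange(shape[0])
    z = origin[2] + pitch * np.arange(shape[2])
    xx, zz = np.meshgrid(x, z, indexing="ij")  # tube cross-section plane

    labels2d = np.zeros(xx.shape, dtype=np.int32)
    for tid, tube in enumerate(config.tubes, start=1):
        r = tube.inner_radius
        if (tube.x - r < x[0] - pitch / 2 or tube.x + r > x[-1] + pitch / 2
                or tube.depth - r < z[0] - pitch / 2
                or tube.depth + r > z[-1] + pitch / 2):
            raise ValueError(f"tube {tid} (x={tube.x}, depth={tube.depth}, "
                             f"r={r}) extends outside the grid")
        mask = (xx - tube.x)**2 + (zz - tube.depth)**2 < r**2
        if not mask.any():
            raise ValueError(f"tube {tid} encloses no voxel centres "
                             f"(radius {r} mm < pitch {pitch} mm?)")
        if np.any(labels2d[mask] != 0):
            raise ValueError(f"tube {tid} overlaps tube "
                             f"{int(labels2d[mask].max())}")
        labels2d[mask] = tid
        unknown = set(tube.concentrations) - set(spectra.names)
        if unknown:
            raise KeyError(f"tube {tid} uses chromophores not in the "
                           f"spectra table: {sorted(unknown)}")

    labels3d = np.repeat(labels2d[:, None, :], shape[1], axis=1)

    conc = {}
    for name in spectra.names:
        vals = np.zeros(shape)
        if name == "water":
            vals[:] = 1.0
        for tid, tube in enumerate(config.tubes, start=1):
            fill = tube.concentrations.get(
                name, 1.0 if name == "water" else 0.0)
            vals[labels3d == tid] = fill
        conc[name] = VoxelGrid(values=vals, pitch=pitch, origin=origin)

    labels = VoxelGrid(values=labels3d.astype(np.float64), pitch=pitch,
                       origin=origin)
    calibrated = [tid for tid, t in enumerate(config.tubes, start=1)
                  if t.calibrated]
    phantom = Phantom(concentrations=conc, spectra=spectra, labels=labels,
                      mus_prime_params=dict(config.mus_prime_params),
                      g=config.g, n_internal=config.n_internal,
                      n_external=config.n_external,
                      gamma_water=config.gamma_water,
                      calibrated_label=calibrated[0] if calibrated else None)
    return phantom, labels
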