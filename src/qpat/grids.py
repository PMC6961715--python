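"""Voxel-grid containers shared by every stage of the pipeline.

Coordinate convention: 0-based voxel indices, the physical coordinate of
voxel ``(i, j, k)`` is ``origin + index * pitch`` (voxel-centre convention).
The planar ultrasound sensor lies at ``z = 0`` and depth increases with
``+z``, matching the depth-from-sensor presentation of planar photoacoustic
scanners.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = ["VoxelGrid", "MultispectralImage"]

#: quantities a multispectral stack may hold
_QUANTITIES = ("p0", "fluence", "absorbed_energy", "concentration")


@dataclass
class VoxelGrid:
    """A 3-D scalar field on an isotropic voxel lattice.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)``; units depend on context.
    pitch
        Isotropic voxel edge length in mm (must be positive).
    origin
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    pitch: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        if not self.pitch > 0:
            raise ValueError(f"voxel pitch must be positive, got {self.pitch}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voxel values must be finite everywhere")
        self.origin = tuple(float(x) for x in self.origin)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, mm^3."""
        return float(self.pitch**3)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.pitch * np.arange(n)

    def index_to_coord(self, index) -> np.ndarray:
        """Voxel index (or ``(..., 3)`` array of indices) to coordinates."""
        return np.asarray(self.origin) + self.pitch * np.asarray(index, dtype=float)

    def coord_to_index(self, coord) -> np.ndarray:
        """Coordinates (mm, last axis = xyz) to fractional voxel indices."""
        return (np.asarray(coord, dtype=float) - np.asarray(self.origin)) / self.pitch

    # -- helpers ----------------------------------------------------------
    def like(self, values: np.ndarray) -> "VoxelGrid":
        """A new grid with the same geometry but different values."""
        if values.shape != self.shape:
            raise ValueError(f"shape mismatch: {values.shape} vs {self.shape}")
        return VoxelGrid(values=np.asarray(values, dtype=np.float64),
                         pitch=self.pitch, origin=self.origin)

    def copy(self) -> "VoxelGrid":
        return replace(self, values=self.values.copy())

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and abs(self.pitch - other.pitch) <= atol
                and np.allclose(self.origin, other.origin, atol=atol))

    @classmethod
    def zeros(cls, shape: tuple[int, int, int], pitch: float,
              origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "VoxelGrid":
        return cls(values=np.zeros(shape), pitch=pitch, origin=origin)


def _check_common_geometry(volumes: Iterable[VoxelGrid]) -> None:
    vols = list(volumes)
    for v in vols[1:]:
        if not vols[0].same_geometry(v):
            raise ValueError("all volumes of a multispectral stack must share "
                             "shape, pitch and origin")


@dataclass
class MultispectralImage:
    """A stack of :class:`VoxelGrid` volumes indexed by excitation wavelength.

    ``quantity`` tags what the scalar field represents: initial pressure
    ``p0``, ``fluence``, ``absorbed_energy`` or ``concentration``.
    """

    wavelengths: list[float]
    volumes: list[VoxelGrid]
    quantity: str = "p0"

    def __post_init__(self) -> None:
        self.wavelengths = [float(w) for w in self.wavelengths]
        if len(self.wavelengths) != len(self.volumes):
            raise ValueError("one volume per wavelength required")
        if len(self.wavelengths) == 0:
            raise ValueError("at least one wavelength required")
        if any(b <= a for a, b in zip(self.wavelengths, self.wavelengths[1:])):
            raise ValueError("wavelengths must be strictly increasing")
        if self.quantity not in _QUANTITIES:
            raise ValueError(f"quantity must be one of {_QUANTITIES}")
        _check_common_geometry(self.volumes)

    def __len__(self) -> int:
        return len(self.wavelengths)

    def __getitem__(self, wavelength: float) -> VoxelGrid:
        for w, v in zip(self.wavelengths, self.volumes):
            if w == float(wavelength):
                return v
        raise KeyError(f"wavelength {wavelength} nm not in stack")

    @property
    def grid(self) -> VoxelGrid:
        """Reference grid (geometry of the first volume)."""
        return self.volumes[0]

    def as_array(self) -> np.ndarray:
        """Stack values into an array of shape ``(n_lambda, nx, ny, nz)``."""
        return np.stack([v.values for v in self.volumes], axis=0)

    def map(self, fn, quantity: str | None = None) -> "MultispectralImage":
        """Apply ``fn(values, wavelength) -> values`` volume-wise."""
        vols = [v.like(np.asarray(fn(v.values, w), dtype=np.float64))
                for w, v in zip(self.wavelengths, self.volumes)]
        return MultispectralImage(wavelengths=list(self.wavelengths), volumes=vols,
                                  quantity=quantity or self.quantity)

    @classmethod
    def from_arrays(cls, wavelengths: Sequence[float], arrays: np.ndarray,
                    pitch: float, origin=(0.0, 0.0, 0.0),
                    quantity: str = "p0") -> "MultispectralImage":
        vols = [VoxelGrid(values=a, pitch=pitch, origin=origin) for a in arrays]
        return cls(wavelengths=list(wavelengths), volumes=vols, quantity=quantity)
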