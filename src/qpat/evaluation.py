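"""Analysis of recovered maps: concentration ratios, sub-volume statistics
and line/tube profiles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import VoxelGrid

__all__ = ["ratio_map", "subvolume_stats", "SubvolumeReport",
           "extract_profile", "tube_profile"]


def ratio_map(c_ni: VoxelGrid, c_cu: VoxelGrid,
              stock_ni: float = 1.54, stock_cu: float = 0.28,
              ) -> tuple[VoxelGrid, np.ndarray]:
    """Stock-normalized concentration ratio R, in percent.

    R = (c_Ni / stock_Ni) / (c_Ni / stock_Ni + c_Cu / stock_Cu) * 100 —
    the blood-oxygen-saturation analogue of a two-solute mixture.  Where
    both normalized concentrations vanish R is undefined; those voxels are
    reported in the validity mask (False) and set to 0 in the map, never
    silently treated as a ratio.
    """
    if stock_ni <= 0 or stock_cu <= 0:
        raise ValueError("stock concentrations must be positive")
    if not c_ni.same_geometry(c_cu):
        raise ValueError("concentration maps must share geometry")
    ni = c_ni.values / stock_ni
    cu = c_cu.values / stock_cu
    denom = ni + cu
    valid = denom > 0
    r = np.zeros_like(denom)
    np.divide(ni, denom, out=r, where=valid)
    return c_ni.like(100.0 * r), valid


@dataclass
class SubvolumeReport:
    """Mean and standard deviation per label per quantity."""

    labels: list[int]
    quantities: list[str]
    mean: np.ndarray        # (n_labels, n_quantities)
    std: np.ndarray
    n_voxels: np.ndarray    # per label

    def row(self, label: int) -> dict[str, tuple[float, float]]:
        i = self.labels.index(label)
        return {q: (float(self.mean[i, j]), float(self.std[i, j]))
                for j, q in enumerate(self.quantities)}

    def to_csv(self, path) -> None:
        header = ["label", "n_voxels"]
        for q in self.quantities:
            header += [f"{q}_mean", f"{q}_sd"]
        rows = []
        for i, lab in enumerate(self.labels):
            row = [str(lab), str(int(self.n_voxels[i]))]
            for j in range(len(self.quantities)):
                row += [f"{self.mean[i, j]:.6g}", f"{self.std[i, j]:.6g}"]
            rows.append(",".join(row))
        with open(path, "w") as fh:
            fh.write(",".join(header) + "\n" + "\n".join(rows) + "\n")


def subvolume_stats(volumes: dict[str, VoxelGrid], labels: VoxelGrid,
                    include_background: bool = True,
                    valid: np.ndarray | None = None) -> SubvolumeReport:
    """Per-label mean/SD of each volume (label 0 = background).

    ``valid`` optionally restricts the statistics of all quantities to a
    voxel subset (e.g. the ratio validity mask).  Labels without any
    (valid) voxel are omitted with a warning.
    """
    lab = labels.values.astype(np.int64)
    ids = sorted(int(v) for v in np.unique(lab))
    if not include_background:
        ids = [v for v in ids if v != 0]
    names = list(volumes)
    kept, mean, std, counts = [], [], [], []
    for lid in ids:
        mask = lab == lid
        if valid is not None:
            mask = mask & valid
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"label {lid} has no (valid) voxels; omitted",
                          stacklevel=2)
            continue
        kept.append(lid)
        counts.append(n)
        mean.append([volumes[q].values[mask].mean() for q in names])
        std.append([volumes[q].values[mask].std() for q in names])
    return SubvolumeReport(labels=kept, quantities=names,
                           mean=np.asarray(mean), std=np.asarray(std),
                           n_voxels=np.asarray(counts))


def extract_profile(volume: VoxelGrid, start, stop,
                    n_samples: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-voxel samples along the line from ``start`` to ``stop`` (mm).

    Returns ``(distance_mm, values)``.  Both endpoints must lie inside the
    volume.
    """
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    for pt in (start, stop):
        idx = volume.coord_to_index(pt)
        if np.any(idx < -0.5) or np.any(idx > np.asarray(volume.shape) - 0.5):
            raise ValueError(f"profile endpoint {pt} lies outside the volume")
    length = float(np.linalg.norm(stop - start))
    if n_samples is None:
        n_samples = max(2, int(np.ceil(length / volume.pitch)) + 1)
    t = np.linspace(0.0, 1.0, n_samples)
    pts = start[None, :] + t[:, None] * (stop - start)[None, :]
    idx = np.rint(volume.coord_to_index(pts)).astype(int)
    idx = np.clip(idx, 0, np.asarray(volume.shape) - 1)
    vals = volume.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return t * length, vals


def tube_profile(volume: VoxelGrid, labels: VoxelGrid, label: int,
                 axis: int = 1, valid: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Cross-section-averaged profile along a tube's axis.

    For each slice along ``axis``, averages ``volume`` over the voxels
    carrying ``label`` (optionally intersected with ``valid``).  Returns
    ``(axis_coordinate_mm, profile)``; slices without labelled voxels hold
    NaN.
    """
    mask = labels.values.astype(np.int64) == int(label)
    if valid is not None:
        mask = mask & valid
    if not mask.any():
        raise ValueError(f"label {label} not present")
    count = mask.sum(axis=tuple(a for a in range(3) if a != axis))
    total = np.where(mask, volume.values, 0.0).sum(
        axis=tuple(a for a in range(3) if a != axis))
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return volume.axis_coords(axis), prof
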