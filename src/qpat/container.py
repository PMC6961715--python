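"""HDF5 container, NIfTI export and YAML configuration round trips.

One HDF5 file carries every artefact a pipeline run touches:

==========================  =================================================
group / dataset             contents
==========================  =================================================
/phantom/concentrations/*   one float volume per chromophore (M / fraction)
/phantom/labels             integer tube labels (0 = background)
/spectra/*                  alpha table, wavelengths, beta, c_max, bounds
/beam/profile               normalized irradiance map + geometry attrs
/fluence/<nm>               MC fluence per wavelength
/forward/<nm>/{mu_a,H,p0}   forward-model fields
/measured/<nm>              measured (or synthetic-measured) images
/corrected/<nm>             limited-view corrected images
/eta                        correction matrix
/series/<nm>                sensor time series (attrs dt, c0)
/calibration/{mask,...}     calibrated-absorber specification
/recovered/*                inversion output volumes
/history                    per-iteration (iteration, epsilon, K, ...) table
==========================  =================================================

Every file records ``schema_version`` and the YAML text of the config that
produced it; arrays round-trip bit-exactly, and datasets the reader does
not recognize are preserved on rewrite.
"""

from __future__ import annotations

import json
from typing import Any

import h5py
import numpy as np
import yaml

from .grids import MultispectralImage, VoxelGrid
from .spectra import ChromophoreSpectra

__all__ = ["SCHEMA_VERSION", "write_container", "read_container",
           "export_nifti", "save_history_csv"]

SCHEMA_VERSION = 1


class SchemaError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# low-level helpers
# ----------------------------------------------------------------------

def _write_grid(group: h5py.Group, name: str, grid: VoxelGrid) -> h5py.Dataset:
    ds = group.create_dataset(name, data=grid.values)
    ds.attrs["pitch_mm"] = grid.pitch
    ds.attrs["origin_mm"] = np.asarray(grid.origin)
    return ds


def _read_grid(ds: h5py.Dataset) -> VoxelGrid:
    return VoxelGrid(values=ds[()], pitch=float(ds.attrs["pitch_mm"]),
                     origin=tuple(ds.attrs["origin_mm"]))


def _write_msi(root: h5py.Group, name: str, msi: MultispectralImage) -> None:
    g = root.create_group(name)
    g.attrs["quantity"] = msi.quantity
    g.attrs["wavelengths_nm"] = np.asarray(msi.wavelengths)
    for lam, vol in zip(msi.wavelengths, msi.volumes):
        _write_grid(g, f"{lam:g}", vol)


def _read_msi(g: h5py.Group) -> MultispectralImage:
    lams = [float(x) for x in g.attrs["wavelengths_nm"]]
    vols = [_read_grid(g[f"{lam:g}"]) for lam in lams]
    return MultispectralImage(lams, vols, quantity=str(g.attrs["quantity"]))


# ----------------------------------------------------------------------
# container API
# ----------------------------------------------------------------------

def write_container(path, bundle: dict[str, Any],
                    config: dict | None = None) -> None:
    """Write a pipeline bundle.

    Recognized keys: ``concentrations`` / ``recovered`` (dict name ->
    VoxelGrid), ``labels`` / ``eta`` (VoxelGrid), ``spectra``
    (ChromophoreSpectra), ``fluence`` / ``measured`` / ``corrected`` /
    ``p0`` (MultispectralImage), ``calibration`` (dict with mask / mu_a /
    gamma / concentrations), ``series`` (dict lam -> (array, dt, c0)),
    ``history`` (list of dicts).  Unknown keys holding plain arrays are
    stored verbatim.
    """
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config_yaml"] = yaml.safe_dump(config or {})
        for key, value in bundle.items():
            if key in ("concentrations", "recovered"):
                base = ("/phantom/concentrations" if key == "concentrations"
                        else "/recovered")
                g = f.require_group(base)
                for name, grid in value.items():
                    _write_grid(g, name, grid)
            elif key == "labels":
                _write_grid(f.require_group("/phantom"), "labels", value)
            elif key == "eta":
                _write_grid(f, "eta", value)
            elif key == "spectra":
                sp: ChromophoreSpectra = value
                g = f.create_group("/spectra")
                g.create_dataset("alpha", data=sp.alpha_table)
                g.create_dataset("wavelengths_nm", data=sp.table_wavelengths)
                g.create_dataset("beta", data=sp.beta)
                g.create_dataset("c_max", data=sp.c_max)
                g.create_dataset("solubility_bounds", data=sp.solubility_bounds)
                g.attrs["names"] = json.dumps(sp.names)
            elif key in ("fluence", "measured", "corrected", "p0"):
                _write_msi(f, f"/{key}", value)
            elif key == "calibration":
                g = f.create_group("/calibration")
                g.create_dataset("mask", data=value["mask"].astype(np.uint8))
                mu = value["mu_a"]
                g.create_dataset("mu_a_wavelengths_nm",
                                 data=np.asarray(sorted(mu)))
                g.create_dataset("mu_a", data=np.asarray(
                    [mu[k] for k in sorted(mu)]))
                g.attrs["gamma"] = value["gamma"]
                if value.get("concentrations"):
                    g.attrs["concentrations"] = json.dumps(
                        value["concentrations"])
            elif key == "series":
                g = f.create_group("/series")
                for lam, (arr, dt, c0) in value.items():
                    ds = g.create_dataset(f"{lam:g}", data=arr)
                    ds.attrs["dt_s"] = dt
                    ds.attrs["c0_m_per_s"] = c0
            elif key == "history":
                if value:
                    cols = list(value[0])
                    g = f.create_group("/history")
                    g.attrs["columns"] = json.dumps(cols)
                    for c in cols:
                        g.create_dataset(c, data=np.asarray(
                            [row[c] for row in value]))
            else:
                f.create_dataset(f"/extra/{key}", data=np.asarray(value))


def read_container(path) -> dict[str, Any]:
    """Read a bundle back; inverse of :func:`write_container`."""
    out: dict[str, Any] = {}
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"container schema version {version} not supported "
                f"(reader supports {SCHEMA_VERSION})")
        out["config"] = yaml.safe_load(f.attrs["config_yaml"]) or {}
        if "phantom" in f:
            if "concentrations" in f["phantom"]:
                out["concentrations"] = {
                    name: _read_grid(ds)
                    for name, ds in f["phantom/concentrations"].items()}
            if "labels" in f["phantom"]:
                out["labels"] = _read_grid(f["phantom/labels"])
        if "eta" in f:
            out["eta"] = _read_grid(f["eta"])
        if "spectra" in f:
            g = f["spectra"]
            out["spectra"] = ChromophoreSpectra(
                names=json.loads(g.attrs["names"]),
                table_wavelengths=g["wavelengths_nm"][()],
                alpha_table=g["alpha"][()],
                beta=g["beta"][()],
                c_max=g["c_max"][()],
                solubility_bounds=g["solubility_bounds"][()])
        for key in ("fluence", "measured", "corrected", "p0"):
            if key in f:
                out[key] = _read_msi(f[key])
        if "calibration" in f:
            g = f["calibration"]
            lams = g["mu_a_wavelengths_nm"][()]
            mu = {float(l): float(v) for l, v in zip(lams, g["mu_a"][()])}
            out["calibration"] = {
                "mask": g["mask"][()].astype(bool), "mu_a": mu,
                "gamma": float(g.attrs["gamma"]),
                "concentrations": (json.loads(g.attrs["concentrations"])
                                   if "concentrations" in g.attrs else None)}
        if "recovered" in f:
            out["recovered"] = {name: _read_grid(ds)
                                for name, ds in f["recovered"].items()}
        if "series" in f:
            out["series"] = {
                float(name): (ds[()], float(ds.attrs["dt_s"]),
                              float(ds.attrs["c0_m_per_s"]))
                for name, ds in f["series"].items()}
        if "history" in f:
            g = f["history"]
            cols = json.loads(g.attrs["columns"])
            n = len(g[cols[0]])
            out["history"] = [
                {c: g[c][i].item() for c in cols} for i in range(n)]
        if "extra" in f:
            for name, ds in f["extra"].items():
                out[name] = ds[()]
    return out


# ----------------------------------------------------------------------
# exports
# ----------------------------------------------------------------------

def export_nifti(grid: VoxelGrid, path) -> None:
    """Write one volume as NIfTI with the voxel pitch in the affine (mm)."""
    import nibabel as nib

    affine = np.diag([grid.pitch, grid.pitch, grid.pitch, 1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(grid.values.astype(np.float32), affine), path)


def save_history_csv(history: list[dict], path) -> None:
    if not history:
        return
    cols = list(history[0])
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in history:
            fh.write(",".join(f"{row[c]:.8g}" if isinstance(row[c], float)
                              else str(row[c]) for c in cols) + "\n")
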