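"""Chromophore absorption spectra and thermoelastic coefficients.

The default fixture emulates a two-solute tissue phantom: aqueous CuSO4 and
NiSO4 mixtures act as photostable analogues of oxy- and deoxyhemoglobin,
with water as the third (background) chromophore.  Solute "concentration"
is molar; the water channel is a volume fraction in [0, 1] whose specific
absorption column is the absorption coefficient of pure water.

The shipped spectra table (``data/spectra_synthetic.csv``) is a synthetic
fixture — smooth curves with the qualitative shape of the real sulfate
spectra (CuSO4 rising into the NIR, NiSO4 peaked near 740 nm) — not a
digitized measurement.  Users with measured spectra substitute their own
table via :meth:`ChromophoreSpectra.from_table`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = ["ChromophoreSpectra", "make_synthetic_spectra", "SpectraRankWarning"]

#: Gruneisen coefficient increments beta_k, 1/M (empirical, water = 0)
DEFAULT_BETA = {"CuSO4": 0.708, "NiSO4": 0.325, "water": 0.0}
#: stock-solution concentrations, M (water: fraction); used as c_max scales
DEFAULT_C_MAX = {"CuSO4": 0.28, "NiSO4": 1.54, "water": 1.0}
#: optimizer upper bounds: sulfate solubility limits, M (water: fraction)
DEFAULT_BOUNDS = {"CuSO4": 1.28, "NiSO4": 2.36, "water": 1.0}


class SpectraRankWarning(UserWarning):
    """Raised when spectra are (near) rank deficient over a wavelength set."""


@dataclass
class ChromophoreSpectra:
    """Specific absorption spectra plus per-chromophore coefficients.

    Parameters
    ----------
    names
        Ordered chromophore identifiers.
    table_wavelengths
        Wavelengths (nm) at which ``alpha_table`` is tabulated, increasing.
    alpha_table
        Specific absorption coefficients, shape ``(n_chromophores,
        n_table_wavelengths)``; mm^-1 M^-1 (for water: mm^-1 per unit
        volume fraction).
    beta
        Gruneisen coefficients beta_k, 1/M; 0 for water.
    c_max
        Maximum plausible concentration per chromophore (M; fraction for
        water).  Only preconditions step sizes — not a hard constraint.
    solubility_bounds
        Upper concentration bound enforced by the optimizer.
    """

    names: list[str]
    table_wavelengths: np.ndarray
    alpha_table: np.ndarray
    beta: np.ndarray
    c_max: np.ndarray
    solubility_bounds: np.ndarray

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.table_wavelengths = np.asarray(self.table_wavelengths, dtype=float)
        self.alpha_table = np.atleast_2d(np.asarray(self.alpha_table, dtype=float))
        self.beta = np.asarray(self.beta, dtype=float)
        self.c_max = np.asarray(self.c_max, dtype=float)
        self.solubility_bounds = np.asarray(self.solubility_bounds, dtype=float)
        n_k, n_l = self.alpha_table.shape
        if n_k != len(self.names):
            raise ValueError("alpha_table rows must match chromophore names")
        if n_l != self.table_wavelengths.size:
            raise ValueError("alpha_table columns must match table wavelengths")
        if np.any(np.diff(self.table_wavelengths) <= 0):
            raise ValueError("table wavelengths must be strictly increasing")
        if np.any(self.alpha_table < 0):
            raise ValueError("specific absorption coefficients must be >= 0")
        if np.any(self.c_max <= 0):
            raise ValueError("c_max must be positive")
        for arr, label in ((self.beta, "beta"), (self.c_max, "c_max"),
                           (self.solubility_bounds, "solubility_bounds")):
            if arr.shape != (n_k,):
                raise ValueError(f"{label} must have one entry per chromophore")

    # ------------------------------------------------------------------
    @property
    def n_chromophores(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def alpha(self, wavelengths: Sequence[float] | float) -> np.ndarray:
        """Specific absorption at arbitrary wavelengths within the table.

        Linear interpolation between tabulated points; wavelengths outside
        the table range raise ``ValueError``.  Returns shape
        ``(n_chromophores, n_wavelengths)`` (squeezed to 1-D for a scalar).
        """
        scalar = np.isscalar(wavelengths)
        lam = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        lo, hi = self.table_wavelengths[0], self.table_wavelengths[-1]
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"wavelength outside spectra table range [{lo}, {hi}] nm")
        out = np.empty((self.n_chromophores, lam.size))
        for k in range(self.n_chromophores):
            out[k] = np.interp(lam, self.table_wavelengths, self.alpha_table[k])
        return out[:, 0] if scalar else out

    def condition_number(self, wavelengths: Sequence[float]) -> float:
        """Condition number of the unmixing matrix over a wavelength set.

        Columns are the per-chromophore spectra scaled by ``c_max`` so the
        number reflects the conditioning of the physically relevant ranges.
        """
        a = self.alpha(wavelengths) * self.c_max[:, None]
        return float(np.linalg.cond(a.T))

    def check_identifiability(self, wavelengths: Sequence[float],
                              cond_limit: float = 1e6) -> float:
        """Warn if the spectra are rank deficient over ``wavelengths``."""
        lam = list(wavelengths)
        cond = np.inf
        if len(lam) >= self.n_chromophores:
            cond = self.condition_number(lam)
        if not np.isfinite(cond) or cond > cond_limit:
            warnings.warn(
                f"spectra are rank deficient or ill conditioned over "
                f"{len(lam)} wavelength(s) ({self.n_chromophores} chromophores, "
                f"cond={cond:.3g}): unmixing is non-unique",
                SpectraRankWarning, stacklevel=2)
        return cond

    # ------------------------------------------------------------------
    @classmethod
    def from_table(cls, names: Sequence[str], wavelengths: Sequence[float],
                   alpha: np.ndarray, beta: Sequence[float],
                   c_max: Sequence[float],
                   solubility_bounds: Sequence[float] | None = None,
                   ) -> "ChromophoreSpectra":
        if solubility_bounds is None:
            solubility_bounds = list(c_max)
        return cls(names=list(names), table_wavelengths=np.asarray(wavelengths),
                   alpha_table=np.asarray(alpha), beta=np.asarray(beta),
                   c_max=np.asarray(c_max),
                   solubility_bounds=np.asarray(solubility_bounds))


def _load_fixture_table() -> tuple[np.ndarray, dict[str, np.ndarray]]:
    path = resources.files("qpat.data").joinpath("spectra_synthetic.csv")
    lam, cols = [], {"CuSO4": [], "NiSO4": [], "water": []}
    with path.open() as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].lstrip().startswith("#")]
    header, body = rows[0], rows[1:]
    for row in body:
        lam.append(float(row[0]))
        cols["CuSO4"].append(float(row[1]))
        cols["NiSO4"].append(float(row[2]))
        cols["water"].append(float(row[3]))
    return np.asarray(lam), {k: np.asarray(v) for k, v in cols.items()}


def make_synthetic_spectra(wavelengths: Sequence[float] | None = None,
                           names: Sequence[str] = ("CuSO4", "NiSO4", "water"),
                           warn_rank: bool = True) -> ChromophoreSpectra:
    """Build the default synthetic phantom spectra.

    Parameters
    ----------
    wavelengths
        If given, the identifiability of the spectra over this excitation
        set is checked (a :class:`SpectraRankWarning` is emitted for a
        rank-deficient system, e.g. fewer wavelengths than chromophores).
    names
        Chromophores to include, a subset of CuSO4 / NiSO4 / water.
    """
    lam, cols = _load_fixture_table()
    names = list(names)
    unknown = set(names) - set(cols)
    if unknown:
        raise KeyError(f"unknown fixture chromophores: {sorted(unknown)}")
    spectra = ChromophoreSpectra(
        names=names,
        table_wavelengths=lam,
        alpha_table=np.stack([cols[n] for n in names]),
        beta=np.array([DEFAULT_BETA[n] for n in names]),
        c_max=np.array([DEFAULT_C_MAX[n] for n in names]),
        solubility_bounds=np.array([DEFAULT_BOUNDS[n] for n in names]),
    )
    if wavelengths is not None and warn_rank:
        spectra.check_identifiability(wavelengths)
    return spectra
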