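"""Voxelized Monte-Carlo photon-packet transport.

Predicts the fluence Phi(r, lambda) per unit incident pulse energy on the
phantom grid.  Packets are launched collimated (+z) from the sensor plane
with entry positions sampled from the beam profile, traverse the voxel
lattice with exact ray stepping, lose weight continuously along each
segment (exp(-mu_a * l)), scatter at free paths sampled from mu_s with a
Henyey-Greenstein phase function, and undergo Russian roulette at low
weight.  Fluence is scored with a track-length estimator, which stays
defined as mu_a -> 0 and has lower variance than absorption-weighted
scoring.

Boundaries: the z=0 (sensor) face applies unpolarized Fresnel reflection
for the internal/external refractive-index step; all other faces of the
padded domain are absorbing.  The domain is padded with a water-only
margin so that backscatter from beyond the image volume is represented;
the returned fluence is cropped to the image grid.

Each packet owns a counter-based RNG stream derived from the master seed,
so results are independent of batching and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .forward import absorption_map
from .grids import VoxelGrid
from .phantom import BeamProfile, Phantom

__all__ = ["McConfig", "McResult", "simulate_fluence", "launch_positions",
           "fresnel_reflectance", "fresnel_boundary"]


@dataclass
class McConfig:
    """Photon-transport run settings.

    ``domain_padding`` voxels of water-only margin are added on the
    lateral and deep faces (the sensor face is never padded).  Roulette
    triggers below ``roulette_threshold`` packet weight with survival
    probability ``roulette_survival``.
    """

    n_photons: int = 50_000
    seed: int = 0
    domain_padding: int = 8
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0 < self.roulette_survival <= 1:
            raise ValueError("roulette_survival must be in (0, 1]")
        if self.domain_padding < 0:
            raise ValueError("domain_padding must be >= 0")


@dataclass
class McResult:
    """Fluence estimate plus the run's energy ledger (per unit launched)."""

    fluence: VoxelGrid
    energy_absorbed: float
    energy_exited: float
    roulette_residual: float
    n_photons: int
    seed: int

    @property
    def energy_balance_error(self) -> float:
        """|absorbed + exited + roulette residual - 1| (launched = 1)."""
        total = self.energy_absorbed + self.energy_exited + self.roulette_residual
        return abs(total - 1.0)


# ----------------------------------------------------------------------
# Fresnel optics (scalar helpers mirrored inside the numba kernel)
# ----------------------------------------------------------------------

def fresnel_reflectance(cos_i: float, n1: float, n2: float) -> float:
    """Unpolarized Fresnel power reflectance for incidence cosine ``cos_i``.

    ``n1`` is the index on the incident side.  Returns 1 beyond the
    critical angle (total internal reflection, only possible for n1 > n2).
    """
    cos_i = abs(float(cos_i))
    sin_t2 = (n1 / n2) ** 2 * (1.0 - cos_i**2)
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


def fresnel_boundary(direction: np.ndarray, n1: float, n2: float, rng,
                     normal=(0.0, 0.0, -1.0)) -> tuple[bool, np.ndarray]:
    """Decide reflection vs transmission at a planar index step.

    ``direction`` is the unit propagation direction, ``normal`` the unit
    interface normal pointing from medium 1 into medium 2 (default: the
    sensor face seen from inside the phantom).  Draws one uniform variate
    from ``rng`` and returns ``(reflected, new_direction)`` with the
    specularly reflected or Snell-refracted unit vector.
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    cos_i = float(np.dot(d, n))
    if cos_i <= 0:
        raise ValueError("direction must head into the interface "
                         "(direction . normal > 0)")
    refl = fresnel_reflectance(cos_i, n1, n2)
    if n1 == n2:
        return False, d
    if rng.random() < refl:
        return True, d - 2.0 * cos_i * n
    ratio = n1 / n2
    sin_t2 = ratio**2 * (1.0 - cos_i**2)
    cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
    return False, ratio * d + (cos_t - ratio * cos_i) * n


# ----------------------------------------------------------------------
# Beam sampling
# ----------------------------------------------------------------------

def _beam_cdf(beam: BeamProfile) -> np.ndarray:
    w = beam.profile.ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("beam has zero total energy")
    return np.cumsum(w) / total


def launch_positions(beam: BeamProfile, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` packet entry positions and (collimated +z) directions.

    Positions are drawn from the discrete beam-pixel distribution and
    jittered uniformly within the pixel; z = 0 (sensor plane).  Returns
    ``(positions (n, 3) mm, directions (n, 3))``.
    """
    cdf = _beam_cdf(beam)
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    nx, ny = beam.profile.shape
    px, py = np.divmod(idx, ny)
    x0 = beam.origin_xy[0] - beam.pitch / 2
    y0 = beam.origin_xy[1] - beam.pitch / 2
    pos = np.empty((n, 3))
    pos[:, 0] = x0 + (px + rng.random(n)) * beam.pitch
    pos[:, 1] = y0 + (py + rng.random(n)) * beam.pitch
    pos[:, 2] = 0.0
    dirs = np.zeros((n, 3))
    dirs[:, 2] = 1.0
    return pos, dirs


# ----------------------------------------------------------------------
# Transport kernel
# ----------------------------------------------------------------------

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _sm64(state):
    """splitmix64: advance state, return (state, uniform double in [0, 1))."""
    state = state + _SM_GAMMA
    z = state
    z = (z ^ (z >> np.uint64(30))) * _SM_M1
    z = (z ^ (z >> np.uint64(27))) * _SM_M2
    z = z ^ (z >> np.uint64(31))
    return state, (z >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True, inline="always")
def _fresnel_r(cos_i, n1, n2):
    sin_t2 = (n1 / n2) ** 2 * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _transport(mu_a, mu_s, g, n_int, n_ext, h,
               n_photons, seed, w_min, p_surv,
               beam_cdf, beam_ny, beam_pitch, beam_x0, beam_y0,
               fluence):
    """Trace ``n_photons`` packets; accumulate track-length fluence.

    ``fluence`` accumulates weight * path-length (mm); the caller divides
    by (n_photons * voxel volume).  Returns (absorbed, exited,
    roulette_residual) energy totals in units of one packet weight.
    """
    nx, ny, nz = mu_a.shape
    absorbed = 0.0
    exited = 0.0
    roulette_net = 0.0
    for ip in range(n_photons):
        state = (np.uint64(seed) + np.uint64(ip) * np.uint64(0x51D9A0E5B8F2D6A7)) \
            ^ np.uint64(0xD1B54A32D192ED03)
        # launch: sample beam pixel via CDF, jitter inside pixel
        state, u = _sm64(state)
        lo = 0
        hi = beam_cdf.size
        while lo < hi:
            mid = (lo + hi) // 2
            if beam_cdf[mid] <= u:
                lo = mid + 1
            else:
                hi = mid
        px = lo // beam_ny
        py = lo - px * beam_ny
        state, u = _sm64(state)
        x = beam_x0 + (px + u) * beam_pitch
        state, u = _sm64(state)
        y = beam_y0 + (py + u) * beam_pitch
        z = 0.0
        if x < 0.0 or x >= nx * h or y < 0.0 or y >= ny * h:
            exited += 1.0  # beam energy missing the padded domain
            continue
        ux = 0.0
        uy = 0.0
        uz = 1.0
        i = int(x / h)
        j = int(y / h)
        k = 0
        w = 1.0
        alive = True
        while alive:
            state, u = _sm64(state)
            tau = -math.log(u + 1e-300)
            scattered = False
            while True:
                mua_v = mu_a[i, j, k]
                mus_v = mu_s[i, j, k]
                # distance to the voxel boundary along the current direction
                t_exit = 1e30
                axis = -1
                sdir = 0
                if ux > 0.0:
                    t = ((i + 1) * h - x) / ux
                    if t < t_exit:
                        t_exit = t
                        axis = 0
                        sdir = 1
                elif ux < 0.0:
                    t = (i * h - x) / ux
                    if t < t_exit:
                        t_exit = t
                        axis = 0
                        sdir = -1
                if uy > 0.0:
                    t = ((j + 1) * h - y) / uy
                    if t < t_exit:
                        t_exit = t
                        axis = 1
                        sdir = 1
                elif uy < 0.0:
                    t = (j * h - y) / uy
                    if t < t_exit:
                        t_exit = t
                        axis = 1
                        sdir = -1
                if uz > 0.0:
                    t = ((k + 1) * h - z) / uz
                    if t < t_exit:
                        t_exit = t
                        axis = 2
                        sdir = 1
                elif uz < 0.0:
                    t = (k * h - z) / uz
                    if t < t_exit:
                        t_exit = t
                        axis = 2
                        sdir = -1
                if t_exit < 0.0:
                    t_exit = 0.0
                if mus_v > 0.0 and mus_v * t_exit >= tau:
                    s = tau / mus_v
                    scattered = True
                else:
                    s = t_exit
                    tau -= mus_v * s
                # deposit along the segment (continuous attenuation)
                if mua_v > 0.0:
                    att = math.exp(-mua_v * s)
                    dep = w * (1.0 - att)
                    fluence[i, j, k] += dep / mua_v
                    absorbed += dep
                    w *= att
                else:
                    fluence[i, j, k] += w * s
                x += ux * s
                y += uy * s
                z += uz * s
                if scattered:
                    break
                # snap to the crossed boundary and advance the index
                if axis == 0:
                    x = (i + (1 if sdir > 0 else 0)) * h
                    i += sdir
                    if i < 0 or i >= nx:
                        exited += w
                        alive = False
                        break
                elif axis == 1:
                    y = (j + (1 if sdir > 0 else 0)) * h
                    j += sdir
                    if j < 0 or j >= ny:
                        exited += w
                        alive = False
                        break
                else:
                    z = (k + (1 if sdir > 0 else 0)) * h
                    k += sdir
                    if k < 0:
                        # sensor face: Fresnel reflect or transmit out
                        state, u = _sm64(state)
                        if u < _fresnel_r(-uz, n_int, n_ext):
                            uz = -uz
                            k = 0
                            z = 0.0
                        else:
                            exited += w
                            alive = False
                            break
                    elif k >= nz:
                        exited += w
                        alive = False
                        break
            if not alive:
                break
            # Henyey-Greenstein scatter
            state, u = _sm64(state)
            if g != 0.0:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            else:
                cost = 2.0 * u - 1.0
            if cost > 1.0:
                cost = 1.0
            elif cost < -1.0:
                cost = -1.0
            sint = math.sqrt(1.0 - cost * cost)
            state, u = _sm64(state)
            phi = 2.0 * math.pi * u
            cosp = math.cos(phi)
            sinp = math.sin(phi)
            if abs(uz) > 0.999999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz > 0.0 else -cost
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                nuy = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                nuz = -sint * cosp * den + uz * cost
                norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux / norm
                uy = nuy / norm
                uz = nuz / norm
            # Russian roulette
            if w < w_min:
                state, u = _sm64(state)
                if u < p_surv:
                    gain = w * (1.0 / p_surv - 1.0)
                    roulette_net -= gain
                    w /= p_surv
                else:
                    roulette_net += w
                    alive = False
    return absorbed, exited, roulette_net


# ----------------------------------------------------------------------
# Driver
# ----------------------------------------------------------------------

def _padded_optics(phantom: Phantom, wavelength: float, padding: int
                   ) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Embed the image-domain optical maps in a water-only padded domain."""
    spectra = phantom.spectra
    grid = phantom.grid
    nx, ny, nz = grid.shape
    p = padding
    shape_p = (nx + 2 * p, ny + 2 * p, nz + p)

    if "water" in spectra.names:
        mua_water = float(spectra.alpha(wavelength)[spectra.index("water")])
    else:
        mua_water = 0.0
    a_bg, b_bg = phantom.mus_prime_params["background"]
    from .phantom import mus_from_mus_prime, mus_prime as _msp
    mus_bg = mus_from_mus_prime(_msp(wavelength, a_bg, b_bg), phantom.g)

    mu_a = np.full(shape_p, mua_water, dtype=np.float64)
    mu_s = np.full(shape_p, mus_bg, dtype=np.float64)
    mu_a[p:p + nx, p:p + ny, 0:nz] = absorption_map(
        phantom.concentrations, spectra, wavelength).values
    mu_s[p:p + nx, p:p + ny, 0:nz] = phantom.mus_volume(wavelength)

    # corner (mm) of padded voxel (0,0,0) in the physical frame
    corner = (grid.origin[0] - grid.pitch / 2 - p * grid.pitch,
              grid.origin[1] - grid.pitch / 2 - p * grid.pitch,
              grid.origin[2] - grid.pitch / 2)
    return mu_a, mu_s, corner


def simulate_fluence(phantom: Phantom, beam: BeamProfile, wavelength: float,
                     config: McConfig) -> McResult:
    """Monte-Carlo fluence Phi(r) at one wavelength, J mm^-2 per J incident.

    Deterministic given ``(config.seed, config, inputs)``.  Scoring runs on
    the padded domain; the returned grid is cropped to the image domain.
    """
    grid = phantom.grid
    h = grid.pitch
    p = config.domain_padding
    mu_a, mu_s, corner = _padded_optics(phantom, wavelength, p)

    cdf = _beam_cdf(beam)
    beam_x0 = (beam.origin_xy[0] - beam.pitch / 2) - corner[0]
    beam_y0 = (beam.origin_xy[1] - beam.pitch / 2) - corner[1]

    fluence = np.zeros_like(mu_a)
    absorbed, exited, roulette_net = _transport(
        mu_a, mu_s, float(phantom.g), float(phantom.n_internal),
        float(phantom.n_external), float(h),
        int(config.n_photons), np.uint64(config.seed & 0xFFFFFFFFFFFFFFFF),
        float(config.roulette_threshold), float(config.roulette_survival),
        cdf, beam.profile.shape[1], float(beam.pitch),
        float(beam_x0), float(beam_y0), fluence)

    nx, ny, nz = grid.shape
    scale = 1.0 / (config.n_photons * grid.voxel_volume)
    cropped = fluence[p:p + nx, p:p + ny, 0:nz] * scale
    return McResult(
        fluence=VoxelGrid(values=cropped, pitch=h, origin=grid.origin),
        energy_absorbed=absorbed / config.n_photons,
        energy_exited=exited / config.n_photons,
        roulette_residual=roulette_net / config.n_photons,
        n_photons=config.n_photons,
        seed=config.seed,
    )
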