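"""Seawater equation of state, compressibility and CTD-derived density profiles.

Density follows the international EOS-80 formulation (UNESCO 1983): the
one-atmosphere equation of Millero & Poisson (1981) combined with the
high-pressure secant bulk modulus.  The implementation is validated against
the published check values (e.g. rho(S=0, T=5, P=0) = 999.96675 kg m^-3,
rho(S=35, T=5, P=0) = 1027.67547 kg m^-3, rho(S=35, T=25, P=1000 bar) =
1062.53817 kg m^-3).

Two compressibility quantities are provided.  ``seawater_compressibility``
is the instantaneous isothermal compressibility kappa = (1/rho) d(rho)/dP
obtained by symmetric finite difference.  ``equivalent_compressibility`` is
the value of the tissue-compressibility parameter r of the glide model that
reproduces seawater's true compression from the surface down to a dive
depth: because the glide model converts depth to pressure at 1 atm per
10 m while seawater actually compresses under ~1 dbar per metre, and
because the model applies r as a secant (finite) compression, the two
quantities differ (0.450e-9 vs 0.463e-9 Pa^-1 for 0 degC, S=35 water over
a 1000 m dive).  The equivalent value is the one comparable with fitted
tissue compressibilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .errors import InsufficientDataError, InvalidStateError

__all__ = [
    "CTDProfile",
    "DensityProfile",
    "seawater_density",
    "seawater_compressibility",
    "equivalent_compressibility",
    "density_profile_from_ctd",
    "read_ctd_csv",
]

# Metres of depth per decibar of hydrostatic pressure (oceanographic
# shallow-water approximation), used only where seawater's *true*
# compression is needed rather than the glide model's pressure convention.
_PA_PER_M_OCEAN = 1.0e4

_T_RANGE = (-2.0, 40.0)
_S_RANGE = (0.0, 42.0)
# Small negative gauge pressures are admitted so that a symmetric
# finite difference can straddle the surface.
_P_MIN = -5.0e4


def _rho_smow(t: np.ndarray) -> np.ndarray:
    """Density of Standard Mean Ocean Water (Bigg 1967), kg m^-3."""
    return (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )


def _rho_one_atm(s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """One-atmosphere density (Millero & Poisson 1981), kg m^-3."""
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return _rho_smow(t) + a * s + b * s**1.5 + c * s**2


def _secant_bulk_modulus(s: np.ndarray, t: np.ndarray, p_bar: np.ndarray) -> np.ndarray:
    """EOS-80 secant bulk modulus K(S, T, P), bar."""
    kw = (
        19652.21
        + 148.4206 * t
        - 2.327105 * t**2
        + 1.360477e-2 * t**3
        - 5.155288e-5 * t**4
    )
    k0 = (
        kw
        + s * (54.6746 - 0.603459 * t + 1.09987e-2 * t**2 - 6.1670e-5 * t**3)
        + s**1.5 * (7.944e-2 + 1.6483e-2 * t - 5.3009e-4 * t**2)
    )
    aw = 3.239908 + 1.43713e-3 * t + 1.16092e-4 * t**2 - 5.77905e-7 * t**3
    a1 = aw + s * (2.2838e-3 - 1.0981e-5 * t - 1.6078e-6 * t**2) + 1.91075e-4 * s**1.5
    bw = 8.50935e-5 - 6.12293e-6 * t + 5.2787e-8 * t**2
    b1 = bw + s * (-9.9348e-7 + 2.0816e-8 * t + 9.1697e-10 * t**2)
    return k0 + a1 * p_bar + b1 * p_bar**2


def _validate_state(temperature, salinity, pressure) -> None:
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    p = np.asarray(pressure, dtype=float)
    if np.any(t < _T_RANGE[0]) or np.any(t > _T_RANGE[1]):
        raise InvalidStateError(f"temperature outside {_T_RANGE} degC")
    if np.any(s < _S_RANGE[0]) or np.any(s > _S_RANGE[1]):
        raise InvalidStateError(f"salinity outside {_S_RANGE} psu")
    if np.any(p < _P_MIN):
        raise InvalidStateError("gauge pressure below supported range")


def seawater_density(temperature, salinity, pressure=0.0):
    """Density of seawater, kg m^-3 (EOS-80).

    Parameters
    ----------
    temperature : float or array
        In-situ temperature, degC, in [-2, 40].
    salinity : float or array
        Practical salinity, psu, in [0, 42].
    pressure : float or array
        Gauge pressure, Pa (0 at the sea surface).
    """
    _validate_state(temperature, salinity, pressure)
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    p_bar = np.asarray(pressure, dtype=float) / 1.0e5
    rho0 = _rho_one_atm(s, t)
    k = _secant_bulk_modulus(s, t, p_bar)
    out = rho0 / (1.0 - p_bar / k)
    if out.ndim == 0:
        return float(out)
    return out


def seawater_compressibility(
    temperature,
    salinity,
    pressure=0.0,
    step: float = 1.0e4,
    density_fn: Callable = seawater_density,
):
    """Instantaneous isothermal compressibility kappa = (1/rho) drho/dP, Pa^-1.

    Computed by symmetric finite difference of ``density_fn`` around
    ``pressure`` with a step of ``step`` Pa; step-halving changes the
    result by <1e-3 relative over oceanic states.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    rho_hi = np.asarray(density_fn(temperature, salinity, pressure + step), dtype=float)
    rho_lo = np.asarray(density_fn(temperature, salinity, pressure - step), dtype=float)
    rho_mid = np.asarray(density_fn(temperature, salinity, pressure), dtype=float)
    if np.any(rho_hi < rho_lo):
        raise ValueError("finite-difference step too large for monotone difference")
    kappa = (rho_hi - rho_lo) / (2.0 * step) / rho_mid
    if kappa.ndim == 0:
        return float(kappa)
    return kappa


def equivalent_compressibility(
    temperature,
    salinity,
    depth: float = 1000.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Glide-model-equivalent compressibility of seawater, Pa^-1.

    The value of the model's tissue-compressibility parameter r that makes
    the tissue-compression law V(d) = V0 * (1 - r * P_model(d)) reproduce
    seawater's actual fractional compression from the surface to ``depth``.
    Seawater's compression is evaluated at the oceanographic hydrostatic
    pressure (~1 dbar per metre); P_model is the model's gauge pressure
    (1 atm per ``constants.m_per_atm`` metres).  Default depth 1000 m, a
    typical deep foraging dive.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    p_ocean = _PA_PER_M_OCEAN * depth
    p_model = constants.atm_pa * depth / constants.m_per_atm
    rho_surface = seawater_density(temperature, salinity, 0.0)
    rho_depth = seawater_density(temperature, salinity, p_ocean)
    return (1.0 - rho_surface / rho_depth) / p_model


@dataclass
class CTDProfile:
    """A depth-indexed temperature/salinity cast.

    ``salinity`` may be a scalar (temperature-only casts are completed with
    a user-supplied constant salinity, default 35 psu).
    """

    depth: np.ndarray
    temperature: np.ndarray
    salinity: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.atleast_1d(np.asarray(self.depth, dtype=float))
        self.temperature = np.atleast_1d(np.asarray(self.temperature, dtype=float))
        sal = np.asarray(self.salinity, dtype=float)
        if sal.ndim == 0:
            sal = np.full_like(self.depth, float(sal))
        self.salinity = sal
        if self.depth.size == 0:
            raise InsufficientDataError("empty CTD profile")
        if not (self.depth.size == self.temperature.size == self.salinity.size):
            raise ValueError("depth, temperature and salinity must have equal length")
        if np.any(self.depth < 0):
            raise ValueError("CTD depths must be non-negative")
        if self.depth.size > 1 and np.any(np.diff(self.depth) <= 0):
            raise ValueError("CTD depths must be strictly increasing")
        _validate_state(self.temperature, self.salinity, 0.0)

    @property
    def max_cast_depth(self) -> float:
        return float(self.depth[-1])


@dataclass
class DensityProfile:
    """Evaluable mapping depth (m) -> ambient seawater density (kg m^-3).

    Within the cast, temperature and salinity are linearly interpolated;
    below the deepest cast point they are held constant while pressure
    keeps increasing with depth, so the profile is continuous and defined
    for all depths >= 0.
    """

    profile: CTDProfile
    constants: PhysicalConstants = field(default=DEFAULT_CONSTANTS)

    def temperature_at(self, depth) -> np.ndarray:
        return np.interp(depth, self.profile.depth, self.profile.temperature)

    def salinity_at(self, depth) -> np.ndarray:
        return np.interp(depth, self.profile.depth, self.profile.salinity)

    def __call__(self, depth):
        d = np.asarray(depth, dtype=float)
        if np.any(d < 0):
            raise ValueError("depth must be non-negative")
        pressure = self.constants.atm_pa * d / self.constants.m_per_atm
        return seawater_density(self.temperature_at(d), self.salinity_at(d), pressure)


def density_profile_from_ctd(
    profile: CTDProfile, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> DensityProfile:
    """Build a depth -> rho_sw function from a CTD cast."""
    return DensityProfile(profile=profile, constants=constants)


def read_ctd_csv(path, default_salinity: float = 35.0) -> CTDProfile:
    """Read a CTD cast from CSV with columns depth_m, temperature_C and
    optionally salinity_psu (filled with ``default_salinity`` when absent)."""
    table = pd.read_csv(path)
    required = {"depth_m", "temperature_C"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"CTD CSV missing columns: {sorted(missing)}")
    if "salinity_psu" in table.columns:
        salinity = table["salinity_psu"].to_numpy(dtype=float)
    else:
        salinity = np.asarray(default_salinity, dtype=float)
    return CTDProfile(
        depth=table["depth_m"].to_numpy(dtype=float),
        temperature=table["temperature_C"].to_numpy(dtype=float),
        salinity=salinity,
    )
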