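"""Forward model of glide dynamics: drag, compressible tissue buoyancy and
Boyle's-law gas buoyancy.

The along-path acceleration of a gliding body is the sum of three terms::

    a = -1/2 * (Cd*A/m) * rho_sw * v^2                       (drag)
        + g * sin(p) * (rho_sw - rho_tissue(d)) / rho_tissue(d)   (tissue)
        + g * sin(p) * (Vair/m)(d) * (rho_sw - rho_air(d))        (gas)

with pitch p negative during descent.  Tissue density increases with depth
through a compressibility factor r applied to the model gauge pressure
(1 atm per 10 m); the gas compartment follows Boyle's law under the
absolute pressure ratio (1 + d/10) atm.  Lift and induced drag are
neglected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .errors import NonPhysicalError

__all__ = [
    "HydroParams",
    "gauge_pressure",
    "tissue_density_at_depth",
    "gas_state_at_depth",
    "glide_acceleration",
    "simulate_glide",
    "GlideTrajectory",
    "terminal_speed",
]

ML_PER_KG_TO_M3_PER_KG = 1.0e-6


@dataclass(frozen=True)
class HydroParams:
    """Parameters of the glide model for one body.

    Attributes
    ----------
    drag_term : float
        Combined (Cd*A)/m, m^2 kg^-1 (typically 5e-6 .. 20e-6).
    rho_tissue : float
        Non-gas tissue density at surface pressure, kg m^-3.
    vair_per_mass : float
        Air carried from the surface per unit body mass, ml kg^-1.
    r : float
        Tissue compressibility, fractional volume decrease per Pa.
    """

    drag_term: float
    rho_tissue: float
    vair_per_mass: float
    r: float

    def __post_init__(self) -> None:
        if self.drag_term < 0:
            raise ValueError("drag_term must be non-negative")
        if not (800.0 <= self.rho_tissue <= 1200.0):
            raise ValueError("rho_tissue outside [800, 1200] kg m^-3")
        if self.vair_per_mass < 0:
            raise ValueError("vair_per_mass must be non-negative")
        if self.r < 0:
            raise ValueError("compressibility r must be non-negative")


def gauge_pressure(depth, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Model gauge pressure at depth, Pa (1 atm per ``m_per_atm`` metres)."""
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    out = constants.atm_pa * d / constants.m_per_atm
    return float(out) if out.ndim == 0 else out


def tissue_density_at_depth(
    rho_tissue, r, depth, constants: PhysicalConstants = DEFAULT_CONSTANTS
):
    """Tissue density at depth, kg m^-3.

    Tissue volume shrinks as V0 * (1 - r*P), so density is
    rho_tissue / (1 - r*P); strictly increasing in depth for r > 0.
    """
    p = gauge_pressure(depth, constants)
    shrink = 1.0 - np.asarray(r, dtype=float) * np.asarray(p, dtype=float)
    if np.any(shrink <= 0):
        raise NonPhysicalError("r*P >= 1: tissue volume would vanish")
    out = np.asarray(rho_tissue, dtype=float) / shrink
    return float(out) if np.ndim(out) == 0 else out


class GasState(NamedTuple):
    volume_per_mass: float  # ml kg^-1 at depth
    rho_air: float  # kg m^-3 at depth


def gas_state_at_depth(
    vair_per_mass, depth, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> GasState:
    """Boyle's-law state of the gas compartment at depth.

    The absolute pressure ratio is q = 1 + d/10 (atm); volume scales as
    1/q and gas density as q, so pressure x volume is conserved.
    """
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    q = 1.0 + d / constants.m_per_atm
    vol = np.asarray(vair_per_mass, dtype=float) / q
    rho_air = constants.rho_air_surface * q
    if vol.ndim == 0:
        return GasState(float(vol), float(rho_air))
    return GasState(vol, rho_air)


def glide_acceleration(
    params: HydroParams,
    v,
    p,
    d,
    rho_sw,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Predicted along-path acceleration during a glide, m s^-2.

    Parameters
    ----------
    v : speed, m s^-1 (non-negative along-path scalar).
    p : pitch, rad, negative downward; |p| <= pi/2.
    d : depth, m.
    rho_sw : ambient seawater density, kg m^-3.
    """
    v = np.asarray(v, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(v < 0):
        raise ValueError("speed must be non-negative")
    if np.any(np.abs(p) > np.pi / 2 + 1e-12):
        raise ValueError("|pitch| must not exceed pi/2")
    rho_sw = np.asarray(rho_sw, dtype=float)
    g = constants.g
    rho_t_d = tissue_density_at_depth(params.rho_tissue, params.r, d, constants)
    vol_ml, rho_air_d = gas_state_at_depth(params.vair_per_mass, d, constants)
    drag = -0.5 * params.drag_term * rho_sw * v**2
    tissue = g * np.sin(p) * (rho_sw - rho_t_d) / rho_t_d
    gas = g * np.sin(p) * (vol_ml * ML_PER_KG_TO_M3_PER_KG) * (rho_sw - rho_air_d)
    out = drag + tissue + gas
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class GlideTrajectory:
    """Speed/depth trajectory of a simulated glide at fixed pitch."""

    time: np.ndarray
    speed: np.ndarray
    depth: np.ndarray
    pitch: float
    truncated: bool = False  # True when speed reached zero before duration


def simulate_glide(
    params: HydroParams,
    v0: float,
    p: float,
    d0: float,
    duration: float,
    dt: float = 0.05,
    density_profile=None,
    rho_sw: Optional[float] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> GlideTrajectory:
    """Integrate the glide dynamics with classical fixed-step RK4.

    State: dv/dt = glide_acceleration, dd/dt = -v*sin(p) (pitch held
    fixed).  Ambient density comes from ``density_profile`` (callable
    depth -> rho_sw) or a constant ``rho_sw``.  The glide terminates early
    (flagged) if speed reaches zero.
    """
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 s for accurate integration")
    if density_profile is None and rho_sw is None:
        raise ValueError("provide density_profile or rho_sw")
    rho_fn = density_profile if density_profile is not None else (lambda d: rho_sw)
    sinp = np.sin(p)

    def deriv(state):
        v, d = state
        v = max(v, 0.0)
        d = max(d, 0.0)
        a = glide_acceleration(params, v, p, d, float(rho_fn(d)), constants)
        return np.array([a, -v * sinp])

    n = int(round(duration / dt))
    times = [0.0]
    speeds = [float(v0)]
    depths = [float(d0)]
    state = np.array([float(v0), float(d0)])
    truncated = False
    for i in range(n):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if state[0] <= 0.0:
            truncated = True
            break
        state[1] = max(state[1], 0.0)
        times.append((i + 1) * dt)
        speeds.append(float(state[0]))
        depths.append(float(state[1]))
    return GlideTrajectory(
        time=np.asarray(times),
        speed=np.asarray(speeds),
        depth=np.asarray(depths),
        pitch=float(p),
        truncated=truncated,
    )


def terminal_speed(
    params: HydroParams,
    p: float,
    d: float,
    rho_sw: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Analytic speed at which drag balances net buoyancy (a = 0).

    Only defined when the buoyancy sum aids motion (positive at v=0);
    raises ValueError otherwise.
    """
    buoy = glide_acceleration(params, 0.0, p, d, rho_sw, constants)
    if buoy <= 0:
        raise ValueError("no terminal speed: net buoyancy opposes motion")
    return float(np.sqrt(2.0 * buoy / (params.drag_term * rho_sw)))
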