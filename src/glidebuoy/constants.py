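"""Physical constants shared across the hydrodynamic model and seawater routines."""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical conventions used throughout the package.

    Attributes
    ----------
    g : float
        Gravitational acceleration, m s^-2.
    atm_pa : float
        One standard atmosphere in pascal; converts the model's
        atmosphere-based pressure bookkeeping to SI.
    m_per_atm : float
        Metres of seawater depth per atmosphere of hydrostatic pressure
        (the model's "1 atm per 10 m" convention).
    rho_air_surface : float
        Density of air at the sea surface, kg m^-3 (15 degC air).
    """

    g: float = 9.8
    atm_pa: float = 101325.0
    m_per_atm: float = 10.0
    rho_air_surface: float = 1.225


DEFAULT_CONSTANTS = PhysicalConstants()
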