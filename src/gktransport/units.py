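"""Physical constants and unit conversions.

Internal unit system (the usual MD conventions): charge in elementary
charges e, mass in amu, length in nm, velocity in nm/ps, time steps in fs,
pressure in bar, temperature in K.  All correlation functions and running
integrals are carried in these raw units; a single property-dependent
prefactor converts a Green-Kubo integral to the SI-facing output unit
(S/m, mPa*s, m^2/s).  Conversions are centralized here so that a
dimensional round trip (raw -> SI -> raw) is the identity to machine
precision.
"""

from __future__ import annotations

import numpy as np

# CODATA 2018 exact values
E_CHARGE = 1.602176634e-19  # C
KB = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

# kB in kJ/(mol K); note 1 kJ/mol == 1 amu nm^2/ps^2, so KB_KJMOL * T is
# the thermal energy in internal kinetic units.
KB_KJMOL = KB * AVOGADRO / 1000.0

# metre equivalents of internal units
NM = 1e-9
PS = 1e-12
FS = 1e-15
BAR = 1e5  # Pa

# 1 amu nm^-1 ps^-2 == 1 kJ mol^-1 nm^-3 expressed in bar
PRESSURE_INTERNAL_TO_BAR = 1000.0 / AVOGADRO / (NM**3) / BAR

#: Yeh-Hummer self-term constant for a cubic periodic box (exact literal).
YEH_HUMMER_XI = 2.8373

PROPERTIES = ("conductivity", "viscosity", "diffusion")


def volume_m3(v_nm3: float) -> float:
    return v_nm3 * NM**3


def gk_prefactor(prop: str, volume_nm3: float | None = None,
                 temperature: float | None = None) -> float:
    """SI conversion factor for a raw Green-Kubo integral.

    The raw integral is assumed to carry the units produced by the
    current calculators in this package:

    - ``conductivity``: integral of an electric-current CAF,
      (e nm/ps)^2 * fs -> multiplied by 1/(V kB T) -> S/m.
    - ``viscosity``: integral of one off-diagonal pressure CAF,
      bar^2 * fs -> multiplied by V/(kB T) -> mPa*s (each off-diagonal
      channel is an independent estimate; channels are combined by the
      isotropic average downstream).
    - ``diffusion``: integral of a single-component COM VACF,
      (nm/ps)^2 * fs -> m^2/s (no V or T needed).
    """
    if prop == "diffusion":
        return (NM / PS) ** 2 * FS
    if volume_nm3 is None or temperature is None:
        raise ValueError(
            f"property {prop!r} is collective: volume and temperature are required"
        )
    if volume_nm3 <= 0 or temperature <= 0:
        raise ValueError("volume and temperature must be positive")
    kbt = KB * temperature
    v = volume_m3(volume_nm3)
    if prop == "conductivity":
        return (E_CHARGE * NM / PS) ** 2 * FS / (v * kbt)
    if prop == "viscosity":
        return BAR**2 * FS * v / kbt * 1e3  # Pa*s -> mPa*s
    raise ValueError(f"unknown property {prop!r}; expected one of {PROPERTIES}")


def einstein_prefactor(prop: str, volume_nm3: float | None = None,
                       temperature: float | None = None) -> float:
    """SI factor for an MSD slope (per ps) in the Einstein route.

    - ``conductivity``: dipole-moment MSD slope in (e nm)^2/ps times
      1/(6 V kB T) -> S/m.
    - ``diffusion``: COM MSD slope in nm^2/ps times 1/6 -> m^2/s.
    """
    if prop == "diffusion":
        return NM**2 / PS / 6.0
    if prop == "conductivity":
        if volume_nm3 is None or temperature is None:
            raise ValueError("conductivity requires volume and temperature")
        return (E_CHARGE * NM) ** 2 / PS / (6.0 * volume_m3(volume_nm3) * KB * temperature)
    raise ValueError(f"no Einstein relation registered for property {prop!r}")


def to_si(raw: float, prop: str, volume_nm3: float | None = None,
          temperature: float | None = None) -> float:
    """Convert a raw GK integral to the property's output unit."""
    return raw * gk_prefactor(prop, volume_nm3, temperature)


def from_si(value: float, prop: str, volume_nm3: float | None = None,
            temperature: float | None = None) -> float:
    """Inverse of :func:`to_si`."""
    return value / gk_prefactor(prop, volume_nm3, temperature)


def output_unit(prop: str) -> str:
    return {"conductivity": "S/m", "viscosity": "mPa*s", "diffusion": "m^2/s"}[prop]


def maxwell_boltzmann_sigma(mass_amu, temperature: float):
    """Per-component velocity standard deviation sqrt(kB T / m) in nm/ps."""
    return np.sqrt(KB_KJMOL * temperature / np.asarray(mass_amu))
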