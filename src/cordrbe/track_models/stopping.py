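"""Oxygen-ion stopping power in water and the beam descriptor.

The embedded table ``data/o16_water_let.csv`` maps specific energy
(MeV/u) to electronic stopping power (keV/um) for 16-O in liquid water.
Provenance: computed from the Bethe formula with the Barkas effective
charge (I = 75 eV, Z/A = 0.5551 for water), valid above ~1 MeV/u; it is
a smooth monoenergetic surrogate for interpolation, not a dosimetric
reference.  ``let_from_energy`` evaluates the same formula directly, so
table and formula can be cross-checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "KEV_PER_UM_TO_GY_UM2",
    "IonBeam",
    "beta_from_energy",
    "let_from_energy",
    "energy_from_let",
    "load_let_table",
]

#: keV/um -> Gy*um^2 (1 keV in 1 um^3 of unit-density water is 0.1602 Gy)
KEV_PER_UM_TO_GY_UM2 = 0.1602

_PROTON_MASS_MEV = 931.4941  # atomic mass unit, MeV
_K_BETHE = 0.307075  # MeV cm^2/g
_ZA_WATER = 0.55509
_I_WATER_MEV = 75.0e-6
_TWO_ME_C2_MEV = 1.021998


def beta_from_energy(energy_mev_u: float) -> float:
    """Relativistic speed ratio v/c from kinetic energy per nucleon."""
    if energy_mev_u <= 0:
        raise ValueError("energy must be positive")
    gamma = 1.0 + energy_mev_u / _PROTON_MASS_MEV
    return math.sqrt(1.0 - 1.0 / (gamma * gamma))


def let_from_energy(energy_mev_u: float, z: int = 8) -> float:
    """Electronic stopping power (keV/um, water) from the Bethe formula."""
    beta = beta_from_energy(energy_mev_u)
    gamma = 1.0 + energy_mev_u / _PROTON_MASS_MEV
    b2 = beta * beta
    z_eff = z * (1.0 - math.exp(-125.0 * beta / z ** (2.0 / 3.0)))
    arg = _TWO_ME_C2_MEV * b2 * gamma * gamma / _I_WATER_MEV
    s = _K_BETHE * _ZA_WATER * (z_eff ** 2 / b2) * (math.log(arg) - b2)
    return s / 10.0  # MeV cm^2/g * (1 g/cm^3) -> keV/um


def load_let_table() -> tuple[np.ndarray, np.ndarray]:
    """(energy MeV/u, LET keV/um) arrays from the embedded table."""
    with resources.files(__package__).joinpath("data/o16_water_let.csv").open() as fh:
        arr = np.loadtxt(fh, delimiter=",", skiprows=1)
    return arr[:, 0], arr[:, 1]


def energy_from_let(let_value: float) -> float:
    """Invert the table on its monotonically decreasing branch (>= 1 MeV/u)."""
    energy, let = load_let_table()
    if not (let.min() <= let_value <= let.max()):
        raise ValueError(
            f"LET {let_value} keV/um outside table range "
            f"[{let.min():.1f}, {let.max():.1f}]")
    # LET decreases with energy on the stored branch: flip for interp
    return float(np.interp(let_value, let[::-1], energy[::-1]))


@dataclass(frozen=True)
class IonBeam:
    """Monoenergetic ion radiation quality.

    Exactly one of ``energy`` / ``let_value`` may be omitted and is then
    derived from the other through the embedded 16-O table.
    """

    z: int = 8
    a: int = 16
    energy: float | None = None  # MeV/u
    let_value: float | None = None  # keV/um, water

    def __post_init__(self) -> None:
        if self.energy is None and self.let_value is None:
            raise ValueError("give energy or let_value")
        if self.energy is None:
            object.__setattr__(self, "energy", energy_from_let(self.let_value))
        if self.let_value is None:
            object.__setattr__(self, "let_value", let_from_energy(self.energy, self.z))
        if self.energy <= 0 or self.let_value <= 0:
            raise ValueError("energy and LET must be positive")

    @property
    def beta_v(self) -> float:
        return beta_from_energy(self.energy)
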