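"""Unit system and physical constants.

Everything inside the package is computed in Hartree atomic units
(hbar = m_e = e = 1, lengths in bohr, energies in hartree).  User-facing
files and reports use angstrom for lengths, elementary charges for charges
and meV for energies by default.

Planck's constant enters the quadrupole (and higher) polarizabilities of a
Drude oscillator; routing every hbar through :class:`UnitSystem` makes the
classical limit (hbar -> 0) a single switch rather than a code change.
"""

from __future__ import annotations

from dataclasses import dataclass

# CODATA 2018
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903
EV_PER_HARTREE = 27.211386245988
MEV_PER_HARTREE = EV_PER_HARTREE * 1e3
KCALMOL_PER_HARTREE = 627.5094740631

#: supported energy unit labels for reports
ENERGY_UNITS = {
    "hartree": 1.0,
    "eV": EV_PER_HARTREE,
    "meV": MEV_PER_HARTREE,
    "kcal/mol": KCALMOL_PER_HARTREE,
}


class InvalidParameterError(ValueError):
    """A physical parameter is outside its allowed domain."""


@dataclass(frozen=True)
class UnitSystem:
    """Atomic-unit system with an adjustable hbar.

    Parameters
    ----------
    hbar:
        Value of the reduced Planck constant in atomic units.  The physical
        value is 1; setting it to ``s`` rescales every explicitly quantum
        quantity (``alpha_l`` for l >= 2 is proportional to hbar**(l-1)),
        and 0 is the classical Drude limit.
    """

    hbar: float = 1.0

    def __post_init__(self) -> None:
        if self.hbar < 0:
            raise InvalidParameterError(f"hbar must be >= 0, got {self.hbar}")

    # -- length ------------------------------------------------------------
    @staticmethod
    def angstrom_to_bohr(x):
        return x * BOHR_PER_ANGSTROM

    @staticmethod
    def bohr_to_angstrom(x):
        return x * ANGSTROM_PER_BOHR

    # -- energy ------------------------------------------------------------
    @staticmethod
    def hartree_to(x, unit: str = "meV"):
        try:
            return x * ENERGY_UNITS[unit]
        except KeyError:
            raise InvalidParameterError(
                f"unknown energy unit {unit!r}; choose from {sorted(ENERGY_UNITS)}"
            ) from None

    @staticmethod
    def to_hartree(x, unit: str = "meV"):
        try:
            return x / ENERGY_UNITS[unit]
        except KeyError:
            raise InvalidParameterError(
                f"unknown energy unit {unit!r}; choose from {sorted(ENERGY_UNITS)}"
            ) from None


#: the default (physical) unit system
AU = UnitSystem()
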