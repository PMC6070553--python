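"""Quantum Drude oscillator parameters and multipole polarizabilities.

A quantum Drude oscillator (QDO) models the valence electronic response of
an atom as a single quasiparticle of mass ``mu`` and charge ``-q`` bound
harmonically (frequency ``omega``) to a fixed center carrying ``+q``.  The
static multipole polarizability of order ``l`` of such an oscillator has
the closed form

    alpha_l = (q^2 / (mu omega^2)) * [(2l-1)!! / l] * (hbar / (2 mu omega))^(l-1)

in atomic units, so the dipole polarizability alpha_1 = q^2/(mu omega^2) is
classical while every higher multipole polarizability is proportional to a
positive power of hbar and vanishes in the classical limit.

Atoms-in-molecules are parameterized Tkatchenko-Scheffler style: free-atom
polarizabilities are rescaled by the Hirshfeld volume ratio V_eff/V_free
(exponent 1 for the dipole, 2 for the quadrupole).  The ratio comes from an
external electronic-structure calculation and defaults to 1 (free atom).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .units import AU, BOHR_PER_ANGSTROM, InvalidParameterError, UnitSystem

__all__ = [
    "QDOParams",
    "AtomSite",
    "alpha_l",
    "classical_limit_alpha_l",
    "ts_scale",
    "params_from_alpha",
    "params_from_polarizabilities",
    "omega_from_c6",
    "load_parameter_table",
    "default_parameter_table",
]


class InvalidMultipoleOrderError(ValueError):
    """Multipole order outside the supported/defined range."""


@dataclass(frozen=True)
class QDOParams:
    """Drude oscillator parameters in Hartree atomic units.

    ``q`` is stored positive; the quasiparticle carries charge ``-q`` and
    the oscillation center ``+q``.
    """

    mu: float
    omega: float
    q: float

    def __post_init__(self) -> None:
        for name in ("mu", "omega", "q"):
            v = getattr(self, name)
            if not v > 0 or not math.isfinite(v):
                raise InvalidParameterError(f"QDOParams.{name} must be positive, got {v}")

    @property
    def alpha1(self) -> float:
        return self.q**2 / (self.mu * self.omega**2)


def alpha_l(params: QDOParams, l: int, units: UnitSystem = AU) -> float:
    """Static multipole polarizability of order ``l`` of one QDO (a.u.).

    Returns ``(q^2/(mu omega^2)) [(2l-1)!!/l] (hbar/(2 mu omega))^(l-1)``,
    in bohr^(2l+1).
    """
    if not isinstance(l, int) or l < 1:
        raise InvalidMultipoleOrderError(f"multipole order must be an integer >= 1, got {l}")
    df = math.prod(range(1, 2 * l, 2))  # (2l-1)!!
    return params.alpha1 * (df / l) * (units.hbar / (2.0 * params.mu * params.omega)) ** (l - 1)


def classical_limit_alpha_l(params: QDOParams, l: int, hbar_scale: float) -> float:
    """``alpha_l`` with hbar replaced by ``hbar_scale * hbar``.

    For ``l >= 2`` the result vanishes as ``hbar_scale -> 0`` (the
    higher-multipole response of a Drude oscillator is a purely quantum
    effect); the dipole polarizability is hbar-independent.
    """
    if hbar_scale < 0:
        raise InvalidParameterError(f"hbar_scale must be >= 0, got {hbar_scale}")
    return alpha_l(params, l, units=UnitSystem(hbar=hbar_scale))


def ts_scale(alpha_free: float, hirshfeld_ratio: float, l: int) -> float:
    """Rescale a free-atom polarizability by the Hirshfeld volume ratio.

    The in-molecule polarizability is ``alpha_free * ratio**l`` with
    exponent 1 for the dipole (l=1) and 2 for the quadrupole (l=2); no rule
    is defined here for higher orders.
    """
    if l not in (1, 2):
        raise InvalidMultipoleOrderError(
            f"Hirshfeld scaling is defined for l in {{1, 2}}, got l={l}"
        )
    if alpha_free < 0:
        raise InvalidParameterError(f"alpha_free must be >= 0, got {alpha_free}")
    if not hirshfeld_ratio > 0:
        raise InvalidParameterError(f"hirshfeld_ratio must be > 0, got {hirshfeld_ratio}")
    return alpha_free * hirshfeld_ratio**l


def params_from_alpha(alpha1: float, omega: float, mu: float = 1.0) -> QDOParams:
    """Drude charge from a target dipole polarizability: q = sqrt(a1 mu w^2)."""
    if not (alpha1 > 0 and omega > 0 and mu > 0):
        raise InvalidParameterError(
            f"alpha1, omega, mu must all be positive, got {alpha1}, {omega}, {mu}"
        )
    return QDOParams(mu=mu, omega=omega, q=math.sqrt(alpha1 * mu * omega**2))


def params_from_polarizabilities(
    alpha1: float, alpha2: float, omega: float, units: UnitSystem = AU
) -> QDOParams:
    """Invert (alpha1, alpha2, omega) -> (mu, omega, q).

    alpha2 = (3/2) alpha1 hbar/(2 mu omega) fixes mu omega = 3 hbar alpha1 /
    (4 alpha2); with omega given this determines mu, and q follows from
    alpha1.  This is the natural closure when a quadrupole polarizability is
    available for each atom.
    """
    if not (alpha1 > 0 and alpha2 > 0 and omega > 0):
        raise InvalidParameterError("alpha1, alpha2, omega must all be positive")
    mu = 3.0 * units.hbar * alpha1 / (4.0 * alpha2 * omega)
    return params_from_alpha(alpha1, omega, mu)


def omega_from_c6(alpha1: float, c6: float) -> float:
    """Characteristic frequency from the identical-atom London relation.

    For two identical Drude oscillators C6 = (3/4) hbar omega alpha1^2, so
    omega = 4 C6 / (3 alpha1^2).  This is a parameterization convention,
    used when a frequency is not supplied directly.
    """
    if not (alpha1 > 0 and c6 > 0):
        raise InvalidParameterError("alpha1 and c6 must be positive")
    return 4.0 * c6 / (3.0 * alpha1**2)


@dataclass
class AtomSite:
    """One atom modeled as a QDO at a fixed center.

    Positions are stored in bohr.  ``alpha1``/``alpha2`` are the effective
    (Hirshfeld-rescaled) polarizabilities actually used in energy formulas;
    ``params`` is the consistent (mu, omega, q) set.
    """

    element: str
    position: tuple[float, float, float]
    params: QDOParams
    hirshfeld_ratio: float = 1.0
    alpha1: float = field(default=0.0)
    alpha2: float = field(default=0.0)
    label: str = ""

    def __post_init__(self) -> None:
        if not self.hirshfeld_ratio > 0:
            raise InvalidParameterError(
                f"hirshfeld_ratio must be > 0, got {self.hirshfeld_ratio}"
            )
        if not self.alpha1:
            self.alpha1 = alpha_l(self.params, 1)
        if not self.alpha2:
            self.alpha2 = alpha_l(self.params, 2)
        if self.alpha1 <= 0 or self.alpha2 < 0:
            raise InvalidParameterError("alpha1 must be > 0 and alpha2 >= 0")
        if not self.label:
            self.label = self.element

    @classmethod
    def from_free_atom(
        cls,
        element: str,
        position_angstrom: tuple[float, float, float],
        table: pd.DataFrame | None = None,
        hirshfeld_ratio: float = 1.0,
        label: str = "",
    ) -> "AtomSite":
        """Build a site from a free-atom parameter table (positions in angstrom).

        Free-atom alpha1/alpha2 are Hirshfeld-rescaled (exponents 1 and 2)
        and the QDO parameters are chosen to reproduce the effective values.
        """
        if table is None:
            table = default_parameter_table()
        key = element.capitalize()
        if key not in table.index:
            raise InvalidParameterError(
                f"element {element!r} not present in parameter table "
                f"(available: {', '.join(table.index)})"
            )
        row = table.loc[key]
        a1 = ts_scale(float(row["alpha1_free"]), hirshfeld_ratio, 1)
        a2 = ts_scale(float(row["alpha2_free"]), hirshfeld_ratio, 2)
        params = params_from_polarizabilities(a1, a2, float(row["omega"]))
        pos = tuple(x * BOHR_PER_ANGSTROM for x in position_angstrom)
        return cls(
            element=key,
            position=pos,  # type: ignore[arg-type]
            params=params,
            hirshfeld_ratio=hirshfeld_ratio,
            alpha1=a1,
            alpha2=a2,
            label=label,
        )


def load_parameter_table(path: str | Path) -> pd.DataFrame:
    """Read a per-element QDO parameter table.

    Whitespace-delimited columns ``element alpha1_free alpha2_free omega``
    (bohr^3, bohr^5, a.u.); ``#`` starts a comment.  Returns a DataFrame
    indexed by element symbol.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        names=["element", "alpha1_free", "alpha2_free", "omega"],
        header=None,
        dtype={"element": str},
    )
    if df.empty:
        raise InvalidParameterError(f"parameter table {path} contains no data rows")
    for col in ("alpha1_free", "alpha2_free", "omega"):
        if not (df[col] > 0).all():
            raise InvalidParameterError(f"parameter table column {col} must be positive")
    df["element"] = df["element"].str.capitalize()
    return df.set_index("element")


def default_parameter_table() -> pd.DataFrame:
    """The small bundled H/C/N/O table (see ``data/qdo_params.dat``)."""
    with resources.as_file(
        resources.files("fidqdo").joinpath("data/qdo_params.dat")
    ) as p:
        return load_parameter_table(p)
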