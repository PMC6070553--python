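"""Complex spherical multipole algebra.

Wigner 3j symbols (Racah formula, exact integer factorials), normalized
irregular solid harmonics, the two-center multipole interaction tensor and
the external-charge coupling coefficients.

Conventions
-----------
Complex spherical harmonics with the Condon-Shortley phase throughout.
The "normalized" (Racah) harmonics are C_lm(rhat) = sqrt(4 pi/(2l+1))
Y_lm(rhat), so that C_l0(z) = 1 on the +z axis.  The irregular solid
harmonic is I_lm(R) = C_lm(Rhat)/|R|^(l+1).

With spherical multipoles Q_lm = sum_i q_i r_i^l C_lm(rhat_i) of two
non-overlapping charge distributions centered a vector R apart (R pointing
from A to B), the electrostatic interaction is

    U = sum Q^A_{lA mA} T_{lA mA; lB mB}(R) Q^B_{lB mB},

    T = (-1)^lA sqrt((2lA+2lB+1)! / ((2lA)! (2lB)!))
        * 3j(lA, lB, lA+lB; mA, mB, -(mA+mB)) * I_{lA+lB, -(mA+mB)}(R),

which reduces on the z axis to the familiar Cartesian dipole-dipole tensor
(T_{10;10} = -2/R^3, T_{1,+1;1,-1} = -1/R^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "wigner3j",
    "irregular_solid_harmonic",
    "interaction_tensor",
    "charge_coupling",
    "InteractionTensor",
    "ChargeCoupling",
    "SingularGeometryError",
    "InvalidIndexError",
]


class InvalidIndexError(ValueError):
    """Angular momentum indices outside their legal range (|m| > l, l < 0)."""


class SingularGeometryError(ValueError):
    """Two interacting centers (or a center and a charge) coincide."""


# --------------------------------------------------------------------------
# Wigner 3j
# --------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _wigner3j_exact(l1: int, l2: int, l3: int, m1: int, m2: int, m3: int):
    """(sign, rational) such that 3j = sign * sqrt(rational); Racah formula."""
    if m1 + m2 + m3 != 0:
        return 0, Fraction(0)
    if l3 < abs(l1 - l2) or l3 > l1 + l2:
        return 0, Fraction(0)
    f = math.factorial
    # triangle coefficient
    tri = Fraction(
        f(l1 + l2 - l3) * f(l1 - l2 + l3) * f(-l1 + l2 + l3), f(l1 + l2 + l3 + 1)
    )
    pref = tri * (
        f(l1 + m1) * f(l1 - m1) * f(l2 + m2) * f(l2 - m2) * f(l3 + m3) * f(l3 - m3)
    )
    tmin = max(0, l2 - l3 - m1, l1 - l3 + m2)
    tmax = min(l1 + l2 - l3, l1 - m1, l2 + m2)
    s = 0
    for t in range(tmin, tmax + 1):
        denom = (
            f(t)
            * f(l3 - l2 + m1 + t)
            * f(l3 - l1 - m2 + t)
            * f(l1 + l2 - l3 - t)
            * f(l1 - m1 - t)
            * f(l2 + m2 - t)
        )
        s += (-1) ** t * Fraction(1, denom)
    if s == 0:
        return 0, Fraction(0)
    phase = (-1) ** (l1 - l2 - m3)
    sign = phase * (1 if s > 0 else -1)
    return sign, pref * s * s


def wigner3j(l1: int, l2: int, l3: int, m1: int, m2: int, m3: int) -> float:
    """Wigner 3j symbol (l1 l2 l3; m1 m2 m3).

    Computed from the Racah single-sum formula with exact integer
    factorial arithmetic, converted to float at the end.  Returns exact 0
    for violated selection rules (m-sum, triangle); raises
    :class:`InvalidIndexError` for structurally invalid indices, which is a
    different situation from a legitimate zero.
    """
    for l, m in ((l1, m1), (l2, m2), (l3, m3)):
        if not (isinstance(l, (int, np.integer)) and isinstance(m, (int, np.integer))):
            raise InvalidIndexError("l and m must be integers")
        if l < 0:
            raise InvalidIndexError(f"l must be >= 0, got {l}")
        if abs(m) > l:
            raise InvalidIndexError(f"|m| <= l required, got l={l}, m={m}")
    sign, rat = _wigner3j_exact(int(l1), int(l2), int(l3), int(m1), int(m2), int(m3))
    return sign * math.sqrt(rat)


# --------------------------------------------------------------------------
# Irregular solid harmonics
# --------------------------------------------------------------------------

def irregular_solid_harmonic(l: int, m: int, R) -> complex:
    """Normalized irregular solid harmonic I_lm(R) (Racah normalization).

    I_lm(R) = sqrt(4 pi/(2l+1)) Y_lm(theta, phi) / |R|^(l+1); on the +z
    axis I_l0 = |R|^-(l+1) and all m != 0 components vanish.
    """
    if abs(m) > l:
        raise InvalidIndexError(f"|m| <= l required, got l={l}, m={m}")
    R = np.asarray(R, dtype=float)
    r = float(np.linalg.norm(R))
    if r <= 0.0:
        raise SingularGeometryError("irregular solid harmonic is singular at R = 0")
    theta = math.acos(max(-1.0, min(1.0, R[2] / r)))
    phi = math.atan2(R[1], R[0])
    y = complex(sph_harm_y(l, m, theta, phi))
    return math.sqrt(4.0 * math.pi / (2 * l + 1)) * y / r ** (l + 1)


# --------------------------------------------------------------------------
# Two-center interaction tensor
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionTensor:
    """One element T_{lA mA; lB mB}(R) of the multipole coupling tensor.

    ``value`` has dimension bohr^-(lA+lB+1); ``separation`` is the vector
    from center A to center B in bohr.
    """

    l_A: int
    m_A: int
    l_B: int
    m_B: int
    separation: tuple[float, float, float]
    value: complex


def interaction_tensor(l_A: int, m_A: int, l_B: int, m_B: int, R) -> InteractionTensor:
    """Multipole interaction tensor element between two centers.

    Indices with |m| > l give an exactly zero element (the operator does
    not exist); a zero separation is a genuine singularity and raises.
    """
    R = np.asarray(R, dtype=float)
    if float(np.linalg.norm(R)) <= 0.0:
        raise SingularGeometryError("interaction tensor is singular at |R| = 0")
    sep = (float(R[0]), float(R[1]), float(R[2]))
    if abs(m_A) > l_A or abs(m_B) > l_B:
        return InteractionTensor(l_A, m_A, l_B, m_B, sep, 0.0 + 0.0j)
    L, M = l_A + l_B, -(m_A + m_B)
    if abs(M) > L:
        return InteractionTensor(l_A, m_A, l_B, m_B, sep, 0.0 + 0.0j)
    pref = (-1) ** l_A * math.sqrt(
        math.factorial(2 * l_A + 2 * l_B + 1)
        / (math.factorial(2 * l_A) * math.factorial(2 * l_B))
    )
    w3j = wigner3j(l_A, l_B, L, m_A, m_B, M)
    val = pref * w3j * irregular_solid_harmonic(L, M, R) if w3j != 0.0 else 0.0 + 0.0j
    return InteractionTensor(l_A, m_A, l_B, m_B, sep, complex(val))


# --------------------------------------------------------------------------
# External point-charge coupling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChargeCoupling:
    """Coefficient of Q_lm in the QDO/external-charge interaction.

    With the quantization axis along the center-to-charge direction the
    coupling Hamiltonian is -delta sum_{l>=1, m} Q_lm / Rtilde^(l+1); this
    object carries the scalar -delta / Rtilde^(l+1) for one (l, m).
    """

    l: int
    m: int
    source_charge: float
    distance: float
    coefficient: float


def charge_coupling(l: int, m: int, delta: float, R_tilde: float) -> ChargeCoupling:
    """Charge-multipole coupling coefficient -delta / Rtilde^(l+1).

    l = 0 is unsupported: the monopole coupling of a neutral QDO is exactly
    compensated between quasiparticle and center.
    """
    if l < 1:
        raise InvalidIndexError(
            "charge coupling is defined for l >= 1 (monopole term cancels for a neutral QDO)"
        )
    if abs(m) > l:
        raise InvalidIndexError(f"|m| <= l required, got l={l}, m={m}")
    if not R_tilde > 0:
        raise SingularGeometryError("charge placed on top of the oscillation center")
    return ChargeCoupling(l, m, delta, R_tilde, -delta / R_tilde ** (l + 1))
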