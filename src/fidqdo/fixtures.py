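"""Deterministic fixture systems for testing and demonstration.

Three presets:

``collinear``
    Two identical oscillators on the z axis with the external charge on the
    perpendicular bisector, so both centers are equidistant from it -- the
    symmetric configuration in which the pair energy collapses to the
    closed form -3 delta alpha2 alpha1 / (Rtilde^2 R^7).  The manifest
    records that expected value.

``bisector``
    Same layout with distances given in angstrom (defaults: Rtilde = 5 A,
    R = 6 A), intended for distance scans at fixed charge distance.

``random-dimer``
    Seeded random small dimer (H/C/N/O atoms with tabulated parameters,
    random Hirshfeld ratios) plus one or two random unit/divalent charges;
    byte-identical regeneration for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np

from .fid import FIDSystem, closed_form_symmetric
from .qdo import AtomSite, default_parameter_table, params_from_polarizabilities
from .units import BOHR_PER_ANGSTROM, InvalidParameterError

__all__ = ["generate_fixture", "PRESETS"]

PRESETS = ("collinear", "bisector", "random-dimer")


def _symmetric_system(r_bohr: float, rtilde_bohr: float, alpha1: float, alpha2: float,
                      omega: float, delta: float) -> FIDSystem:
    if rtilde_bohr <= r_bohr / 2.0:
        raise InvalidParameterError(
            f"equal charge distances require Rtilde > R/2 (got Rtilde={rtilde_bohr}, R={r_bohr})"
        )
    params = params_from_polarizabilities(alpha1, alpha2, omega)
    a = AtomSite("H", (0.0, 0.0, 0.0), params, alpha1=alpha1, alpha2=alpha2, label="A")
    b = AtomSite("H", (0.0, 0.0, r_bohr), params, alpha1=alpha1, alpha2=alpha2, label="B")
    x = math.sqrt(rtilde_bohr**2 - (r_bohr / 2.0) ** 2)
    return FIDSystem([a], [b], [((x, 0.0, r_bohr / 2.0), delta)])


def generate_fixture(preset: str, seed: int = 0, **kw):
    """Build a preset FIDSystem and a manifest of expected values.

    Returns ``(system, manifest)``; the manifest records the preset
    parameters and, where a closed form exists, the expected FID energy.
    """
    if preset == "collinear":
        alpha1 = kw.pop("alpha1", 1.0)
        alpha2 = kw.pop("alpha2", 1.0)
        omega = kw.pop("omega", 1.0)
        delta = kw.pop("delta", 1.0)
        r = kw.pop("r_bohr", 1.0)
        rtilde = kw.pop("rtilde_bohr", 1.0)
        _reject_extra(kw)
        system = _symmetric_system(r, rtilde, alpha1, alpha2, omega, delta)
        expected = closed_form_symmetric(alpha1, alpha2, delta, rtilde, r)
        manifest = {
            "preset": preset,
            "alpha1_au": alpha1,
            "alpha2_au": alpha2,
            "omega_au": omega,
            "delta_e": delta,
            "r_bohr": r,
            "rtilde_bohr": rtilde,
            "expected_fid_hartree": expected,
        }
        return system, manifest

    if preset == "bisector":
        alpha1 = kw.pop("alpha1", 1.0)
        alpha2 = kw.pop("alpha2", 1.0)
        omega = kw.pop("omega", 1.0)
        delta = kw.pop("delta", 1.0)
        r_ang = kw.pop("r_angstrom", 6.0)
        rt_ang = kw.pop("rtilde_angstrom", 5.0)
        _reject_extra(kw)
        r = r_ang * BOHR_PER_ANGSTROM
        rtilde = rt_ang * BOHR_PER_ANGSTROM
        system = _symmetric_system(r, rtilde, alpha1, alpha2, omega, delta)
        expected = closed_form_symmetric(alpha1, alpha2, delta, rtilde, r)
        manifest = {
            "preset": preset,
            "alpha1_au": alpha1,
            "alpha2_au": alpha2,
            "omega_au": omega,
            "delta_e": delta,
            "r_angstrom": r_ang,
            "rtilde_angstrom": rt_ang,
            "expected_fid_hartree": expected,
        }
        return system, manifest

    if preset == "random-dimer":
        n_a = kw.pop("n_atoms_a", 2)
        n_b = kw.pop("n_atoms_b", 2)
        n_charges = kw.pop("n_charges", 1)
        _reject_extra(kw)
        rng = np.random.default_rng(seed)
        table = default_parameter_table()
        elements = list(table.index)

        def frag(n, center, tag):
            sites = []
            for i in range(n):
                el = elements[rng.integers(len(elements))]
                pos = center + rng.uniform(-1.2, 1.2, size=3)
                ratio = float(rng.uniform(0.7, 1.1))
                sites.append(
                    AtomSite.from_free_atom(
                        el, tuple(pos), table, hirshfeld_ratio=ratio, label=f"{tag}{i + 1}"
                    )
                )
            return sites

        frag_a = frag(n_a, np.zeros(3), "A")
        frag_b = frag(n_b, np.array([0.0, 0.0, 5.0]), "B")
        charges = []
        for _ in range(n_charges):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = np.array([0.0, 0.0, 2.5]) + direction * rng.uniform(4.0, 7.0)
            delta = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
            charges.append(
                ((pos[0] * BOHR_PER_ANGSTROM, pos[1] * BOHR_PER_ANGSTROM,
                  pos[2] * BOHR_PER_ANGSTROM), delta)
            )
        system = FIDSystem(frag_a, frag_b, charges)
        manifest = {
            "preset": preset,
            "seed": seed,
            "n_atoms": n_a + n_b,
            "n_charges": n_charges,
            "elements": [s.element for s in system.sites],
        }
        return system, manifest

    raise InvalidParameterError(f"unknown preset {preset!r}; choose from {PRESETS}")


def _reject_extra(kw: dict) -> None:
    if kw:
        raise InvalidParameterError(f"unknown fixture parameters {sorted(kw)}")
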