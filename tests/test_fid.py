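"""The analytic field-induced dispersion energy and its invariants."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fidqdo.fid import (
    FIDSystem,
    antisymmetric_combination,
    binding_fraction,
    closed_form_symmetric,
    fid_pair_polarized,
    fid_pair_total,
    fid_system,
    london_pair_c6,
)
from fidqdo.qdo import AtomSite, params_from_polarizabilities
from fidqdo.tensors import SingularGeometryError
from fidqdo.units import InvalidParameterError, UnitSystem

from conftest import random_site


class TestClosedForm:
    def test_unit_case_prefactor(self):
        assert closed_form_symmetric(1.0, 1.0, 1.0, 1.0, 1.0) == pytest.approx(-3.0)

    def test_negative_charge_flips_sign(self):
        assert closed_form_symmetric(1.0, 1.0, -1.0, 1.0, 1.0) == pytest.approx(3.0)

    def test_distance_power(self):
        e1 = closed_form_symmetric(1.0, 1.0, 1.0, 2.0, 3.0)
        e2 = closed_form_symmetric(1.0, 1.0, 1.0, 2.0, 6.0)
        assert e2 / e1 == pytest.approx(2.0**-7, rel=1e-14)

    def test_bad_distances(self):
        with pytest.raises(SingularGeometryError):
            closed_form_symmetric(1, 1, 1, 0.0, 1.0)


class TestPairEnergy:
    def test_zero_charge(self, unit_pair):
        a, b = unit_pair
        assert fid_pair_polarized(a, b, 0.0, 3.0, (0, 0, 5.0)) == 0.0

    def test_equal_frequency_factor(self, unit_pair):
        """For omega_A = omega_B the frequency factor is exactly 1/6."""
        a, b = unit_pair
        e = fid_pair_polarized(a, b, 1.0, 3.0, (0, 0, 5.0))
        expected = -0.5 * 1.0 * 1.0 * (1.0 / 6.0) / 3.0**2 * 18.0 / 5.0**7
        assert e == pytest.approx(expected, rel=1e-12)

    def test_symmetric_case_equals_closed_form(self, unit_pair):
        """Identical sites, equal charge distances: pair total == closed form."""
        a, b = unit_pair
        total = fid_pair_total(a, b, 1.0, 7.0, 7.0, (0, 0, 5.0))
        assert total == pytest.approx(
            closed_form_symmetric(1.0, 1.0, 1.0, 7.0, 5.0), rel=1e-10
        )
        single = fid_pair_polarized(a, b, 1.0, 7.0, (0, 0, 5.0))
        assert total == pytest.approx(2.0 * single, rel=1e-12)

    def test_exact_delta_antisymmetry(self, rng):
        for _ in range(10):
            a = random_site(rng, rng.normal(size=3), "A")
            b = random_site(rng, rng.normal(size=3) + np.array([0, 0, 6.0]), "B")
            r_ab = np.asarray(b.position) - np.asarray(a.position)
            rta, rtb = rng.uniform(3, 12, size=2)
            ep = fid_pair_total(a, b, 1.7, rta, rtb, r_ab)
            em = fid_pair_total(a, b, -1.7, rta, rtb, r_ab)
            assert em == -ep  # exact, machine precision

    def test_sign_rule_positive_charge_stabilizes(self, rng):
        for _ in range(10):
            a = random_site(rng, rng.normal(size=3), "A")
            b = random_site(rng, rng.normal(size=3) + np.array([0, 0, 7.0]), "B")
            r_ab = np.asarray(b.position) - np.asarray(a.position)
            e = fid_pair_total(a, b, float(rng.uniform(0.5, 2)), 5.0, 8.0, r_ab)
            assert e < 0.0

    def test_linear_in_delta(self, unit_pair):
        a, b = unit_pair
        e1 = fid_pair_total(a, b, 0.5, 4.0, 6.0, (0, 0, 5.0))
        e2 = fid_pair_total(a, b, 2.0, 4.0, 6.0, (0, 0, 5.0))
        assert e2 == pytest.approx(4.0 * e1, rel=1e-14)

    def test_r_power_law_minus_7(self, unit_pair):
        a, b0 = unit_pair
        rs = np.geomspace(8.0, 80.0, 7)
        es = []
        for r in rs:
            b = AtomSite("H", (0, 0, float(r)), b0.params, alpha1=1.0, alpha2=1.0)
            es.append(abs(fid_pair_total(a, b, 1.0, 5.0, 5.0, (0, 0, float(r)))))
        slope = np.polyfit(np.log(rs), np.log(es), 1)[0]
        assert slope == pytest.approx(-7.0, abs=1e-6)

    def test_rtilde_power_law_minus_2(self, unit_pair):
        a, b = unit_pair
        rts = np.geomspace(3.0, 30.0, 7)
        es = [abs(fid_pair_polarized(a, b, 1.0, float(rt), (0, 0, 5.0))) for rt in rts]
        slope = np.polyfit(np.log(rts), np.log(es), 1)[0]
        assert slope == pytest.approx(-2.0, abs=1e-6)

    def test_classical_limit_linear_in_hbar(self, unit_pair):
        """FID vanishes linearly with hbar (through the quadrupole response)."""
        a, b = unit_pair
        full = fid_pair_total(a, b, 1.0, 4.0, 6.0, (0, 0, 5.0))
        half = fid_pair_total(a, b, 1.0, 4.0, 6.0, (0, 0, 5.0), units=UnitSystem(hbar=0.5))
        zero = fid_pair_total(a, b, 1.0, 4.0, 6.0, (0, 0, 5.0), units=UnitSystem(hbar=0.0))
        assert half == pytest.approx(0.5 * full, rel=1e-14)
        assert zero == 0.0

    def test_missing_quadrupole_rejected(self, unit_pair):
        a, b = unit_pair
        bad = AtomSite("H", (0, 0, 0), a.params, alpha1=1.0, alpha2=1e-30)
        bad.alpha2 = 0.0
        with pytest.raises(InvalidParameterError):
            fid_pair_polarized(bad, b, 1.0, 3.0, (0, 0, 5.0))


class TestLondonC6:
    def test_identical_sites(self, unit_pair):
        a, b = unit_pair
        w = a.params.omega
        assert london_pair_c6(a, b) == pytest.approx(0.75 * w * 1.0, rel=1e-12)

    def test_saturation_limit(self):
        pa = params_from_polarizabilities(2.0, 2.0, 0.5)
        a = AtomSite("H", (0, 0, 0), pa, alpha1=2.0, alpha2=2.0)
        prev = 0.0
        for wb in (0.5, 2.0, 8.0, 32.0, 128.0):
            pb = params_from_polarizabilities(3.0, 3.0, wb)
            b = AtomSite("H", (0, 0, 5), pb, alpha1=3.0, alpha2=3.0)
            c6 = london_pair_c6(a, b)
            assert c6 > prev
            prev = c6
        limit = 1.5 * 2.0 * 3.0 * 0.5
        assert prev < limit
        assert prev == pytest.approx(limit, rel=0.01)


class TestDiagnostics:
    def test_antisymmetric_combination(self):
        assert antisymmetric_combination(47.4, -47.4) == pytest.approx(47.4)
        assert antisymmetric_combination(3.3, 3.3) == 0.0
        em = closed_form_symmetric(1.0, 1.0, -1.3, 2.0, 3.0)
        ep = closed_form_symmetric(1.0, 1.0, 1.3, 2.0, 3.0)
        assert antisymmetric_combination(em, ep) == pytest.approx(-ep)

    def test_binding_fraction(self):
        assert binding_fraction(47.4, 134.6) == pytest.approx(35.2, abs=0.05)
        assert binding_fraction(0.0, 10.0) == 0.0
        assert binding_fraction(26.2, 134.2) == pytest.approx(19.5, abs=0.05)
        with pytest.raises(InvalidParameterError):
            binding_fraction(1.0, 0.0)


class TestSystemAggregation:
    def test_single_pair_reduction(self, unit_pair):
        a, b = unit_pair
        charge = ((3.0, 0.0, -2.0), 1.5)
        system = FIDSystem([a], [b], [charge])
        report = fid_system(system)
        p = np.asarray(charge[0])
        rta = float(np.linalg.norm(p - np.asarray(a.position)))
        rtb = float(np.linalg.norm(p - np.asarray(b.position)))
        direct = fid_pair_total(a, b, 1.5, rta, rtb, (0, 0, 5.0))
        assert report.total == pytest.approx(direct, rel=1e-12)
        assert len(report.entries) == 1

    def test_charge_superposition(self, unit_pair):
        a, b = unit_pair
        pos = (4.0, 0.0, 1.0)
        two = fid_system(FIDSystem([a], [b], [(pos, 1.0), (pos, 1.0)]))
        one = fid_system(FIDSystem([a], [b], [(pos, 2.0)]))
        assert two.total == pytest.approx(one.total, rel=1e-14)

    def test_charge_negation_flips_every_entry(self, rng):
        frag_a = [random_site(rng, rng.normal(size=3), f"A{i}") for i in range(2)]
        frag_b = [random_site(rng, rng.normal(size=3) + np.array([0, 0, 8.0]), f"B{i}")
                  for i in range(2)]
        charges = [(tuple(rng.normal(size=3) + np.array([6, 0, 4])), 1.0),
                   (tuple(rng.normal(size=3) - np.array([6, 0, 0])), -2.0)]
        system = FIDSystem(frag_a, frag_b, charges)
        rep = fid_system(system)
        rep_neg = fid_system(system.negated_charges())
        assert rep_neg.total == -rep.total
        for e, en in zip(rep.entries, rep_neg.entries):
            assert en["pair_total"] == -e["pair_total"]

    def test_total_is_sum_of_entries(self, rng):
        frag_a = [random_site(rng, rng.normal(size=3), f"A{i}") for i in range(3)]
        frag_b = [random_site(rng, rng.normal(size=3) + np.array([0, 0, 9.0]), f"B{i}")
                  for i in range(2)]
        system = FIDSystem(frag_a, frag_b, [((7.0, 1.0, 2.0), 1.0)])
        rep = fid_system(system)
        assert rep.total == pytest.approx(
            sum(e["pair_total"] for e in rep.entries), rel=1e-10
        )
        assert len(rep.entries) == 6

    def test_rigid_rotation_invariance(self, rng):
        frag_a = [random_site(rng, rng.normal(size=3), f"A{i}") for i in range(2)]
        frag_b = [random_site(rng, rng.normal(size=3) + np.array([0, 0, 8.0]), f"B{i}")
                  for i in range(2)]
        charges = [((5.0, -3.0, 2.0), 1.0)]
        base = fid_system(FIDSystem(frag_a, frag_b, charges)).total
        for _ in range(20):
            rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()

            def rotated(site, tag):
                return AtomSite(site.element, tuple(rot @ np.asarray(site.position)),
                                site.params, alpha1=site.alpha1, alpha2=site.alpha2,
                                label=tag)

            ra = [rotated(s, s.label) for s in frag_a]
            rb = [rotated(s, s.label) for s in frag_b]
            rc = [(tuple(rot @ np.asarray(p)), d) for p, d in charges]
            total = fid_system(FIDSystem(ra, rb, rc)).total
            assert total == pytest.approx(base, rel=1e-9)

    def test_include_intra_adds_pairs(self, rng):
        frag_a = [random_site(rng, rng.normal(size=3), f"A{i}") for i in range(2)]
        frag_b = [random_site(rng, rng.normal(size=3) + np.array([0, 0, 8.0]), "B0")]
        system = FIDSystem(frag_a, frag_b, [((6.0, 0.0, 0.0), 1.0)])
        inter = fid_system(system)
        both = fid_system(system, include_intra=True)
        assert len(both.entries) == len(inter.entries) + 1

    def test_empty_fragment_rejected(self, unit_pair):
        a, _ = unit_pair
        with pytest.raises(InvalidParameterError):
            FIDSystem([a], [], [])

    def test_overlapping_charge_rejected(self, unit_pair):
        a, b = unit_pair
        with pytest.raises(SingularGeometryError):
            FIDSystem([a], [b], [((0.0, 0.0, 0.0), 1.0)])

    def test_report_units(self, unit_pair):
        a, b = unit_pair
        rep = fid_system(FIDSystem([a], [b], [((4.0, 0.0, 0.0), 1.0)]))
        d = rep.to_dict("meV")
        assert d["total_fid"] == pytest.approx(rep.total * 27211.386245988, rel=1e-12)
        assert d["units"]["energy"] == "meV"

    def test_london_comparator_energy(self, unit_pair):
        a, b = unit_pair
        rep = fid_system(FIDSystem([a], [b], [((4.0, 0.0, 0.0), 1.0)]))
        assert rep.london_energy == pytest.approx(-london_pair_c6(a, b) / 5.0**6, rel=1e-12)

    def test_summary_table(self, unit_pair):
        from fidqdo.fid import report_table

        a, b = unit_pair
        rep = fid_system(FIDSystem([a], [b], [((4.0, 0.0, 0.0), 1.0)]))
        df = report_table(rep, binding_energy=100.0, unit="meV")
        assert df.shape == (1, 3)
        assert df.loc[0, "FID_percent_of_binding"] == pytest.approx(
            rep.total_in("meV"), rel=1e-12
        )
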