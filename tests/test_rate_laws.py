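"""Elementary rate laws: printed examples, limits and invariants."""

import math

import pytest
import sympy
from hypothesis import given, settings, strategies as st

from isogly.rate_laws import (
    IsoenzymeKinetics,
    first_order,
    mm_irreversible,
    mm_reversible,
    reaction_rate,
    substrate_inhibition,
)

conc = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)
pos = st.floats(min_value=1e-3, max_value=100.0, allow_nan=False)


class TestMichaelisMenten:
    def test_zero_substrate(self):
        assert mm_irreversible(1.0, 10.0, 0.0, 0.1) == 0.0

    def test_half_saturation(self):
        assert mm_irreversible(1.0, 10.0, 0.1, 0.1) == pytest.approx(5.0)

    def test_hxk2_limiting_rate_at_saturation(self):
        # E from the proteome (185000 copies at 5 fl), kcat 63.1/s; at
        # S >> Km the rate approaches E*kcat ~ 3.877 mM/s
        E = 0.0614399
        v = mm_irreversible(E, 63.1, 1e6, 0.2)
        assert v == pytest.approx(E * 63.1, rel=1e-6)
        assert v == pytest.approx(3.877, abs=2e-3)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(E=pos, kcat=pos, s=conc, km=pos)
    def test_bounded_by_limiting_rate_and_monotone(self, E, kcat, s, km):
        v = mm_irreversible(E, kcat, s, km)
        assert 0.0 <= v <= E * kcat + 1e-12
        assert mm_irreversible(E, kcat, s + 1.0, km) >= v - 1e-12

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ValueError):
            mm_irreversible(1.0, 1.0, 1.0, 0.0)


class TestSubstrateInhibition:
    def test_zero_substrate(self):
        assert substrate_inhibition(2.0, 564.0, 0.0, 6.45, 35.1) == 0.0

    def test_tpi_parameters_by_symbolic_substitution(self):
        """Direct substitution of the triose-phosphate-isomerase constants,
        checked against an independent exact-rational evaluation."""
        E, kcat, S, Km, Ki = 1, 564, sympy.Rational(645, 100), sympy.Rational(645, 100), sympy.Rational(351, 10)
        expected = E * kcat * S / (Km + S * (1 + (S / Ki) ** 4))
        v = substrate_inhibition(1.0, 564.0, 6.45, 6.45, 35.1)
        assert v == pytest.approx(float(expected), rel=1e-12)

    def test_ki_limit_recovers_michaelis_menten(self):
        v_inf = substrate_inhibition(1.0, 10.0, 2.0, 0.5, 1e9)
        assert v_inf == pytest.approx(mm_irreversible(1.0, 10.0, 2.0, 0.5), rel=1e-9)

    def test_vanishes_at_high_substrate_with_interior_maximum(self):
        s_grid = [0.01 * 1.3 ** i for i in range(60)]
        v = [substrate_inhibition(1.0, 564.0, s, 6.45, 35.1) for s in s_grid]
        peak = max(range(len(v)), key=v.__getitem__)
        assert 0 < peak < len(v) - 1
        assert v[-1] < 0.05 * v[peak]
        # single sign change of the difference sequence: unique maximum
        signs = [b - a for a, b in zip(v, v[1:])]
        changes = sum(1 for a, b in zip(signs, signs[1:]) if a > 0 >= b)
        assert changes == 1

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(E=pos, kcat=pos, s=conc, km=pos, ki=pos)
    def test_never_exceeds_michaelis_menten(self, E, kcat, s, km, ki):
        assert substrate_inhibition(E, kcat, s, km, ki) <= (
            mm_irreversible(E, kcat, s, km) + 1e-12
        )

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(ValueError):
            substrate_inhibition(1.0, 1.0, 1.0, 1.0, 0.0)


class TestReversibleMM:
    def test_equilibrium_is_exact_zero(self):
        assert mm_reversible(1.0, 5.0, 2.0, 2.0 * 3.5, 0.5, 1.0, 3.5) == pytest.approx(0.0, abs=1e-15)

    def test_zero_product_reduces_to_irreversible(self):
        v = mm_reversible(1.0, 5.0, 2.0, 0.0, 0.5, 1.0, 3.5)
        assert v == pytest.approx(mm_irreversible(1.0, 5.0, 2.0, 0.5), rel=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(s=conc, p=conc, keq=pos)
    def test_sign_matches_thermodynamic_drive(self, s, p, keq):
        v = mm_reversible(1.0, 5.0, s, p, 0.5, 1.0, keq)
        drive = keq * s - p
        assert math.copysign(1.0, v) == math.copysign(1.0, drive) or drive == 0 or v == 0

    def test_nonpositive_keq_rejected(self):
        with pytest.raises(ValueError):
            mm_reversible(1, 1, 1, 1, 1, 1, 0.0)


class TestFirstOrder:
    def test_succinate_branch_prefit_value(self):
        assert first_order(0.005, 2.109) == pytest.approx(0.010545, rel=1e-12)

    def test_turned_off_branch(self):
        assert first_order(0.0, 123.0) == 0.0
        assert first_order(0.37, 0.0) == 0.0


class TestReactionRate:
    HXK = [
        (IsoenzymeKinetics("Glk1p", "mm_irreversible", 0.0721,
                           {"GLC": 0.0106, "ATP": 0.865}), 0.0452),
        (IsoenzymeKinetics("Hxk1p", "mm_irreversible", 10.2,
                           {"GLC": 0.15, "ATP": 0.293}), 0.0168),
        (IsoenzymeKinetics("Hxk2p", "mm_irreversible", 63.1,
                           {"GLC": 0.2, "ATP": 0.195}), 0.0614),
    ]
    C = {"GLC": 1.0, "ATP": 2.0}

    def test_single_isoenzyme_equals_own_law(self):
        kin, E = self.HXK[2]
        expected = (E * 63.1 * self.C["GLC"] / (0.2 + self.C["GLC"])
                    * self.C["ATP"] / (0.195 + self.C["ATP"]))
        assert reaction_rate([(kin, E)], self.C) == pytest.approx(expected, rel=1e-12)

    def test_inactive_isoenzyme_contributes_nothing(self):
        dead = IsoenzymeKinetics("Adh5p", "mm_irreversible", 0.0, {"ACE": 1.0})
        live = IsoenzymeKinetics("Adh1p", "mm_irreversible", 176.0, {"ACE": 0.462})
        c = {"ACE": 1.0}
        assert reaction_rate([(live, 0.1), (dead, 0.1)], c) == pytest.approx(
            reaction_rate([(live, 0.1)], c), rel=1e-14
        )

    def test_additivity_over_isoenzymes(self):
        total = reaction_rate(self.HXK, self.C)
        parts = sum(reaction_rate([pair], self.C) for pair in self.HXK)
        assert total == pytest.approx(parts, rel=1e-14)

    def test_linearity_in_each_enzyme_level(self):
        kin, E = self.HXK[1]
        assert reaction_rate([(kin, 2 * E)], self.C) == pytest.approx(
            2 * reaction_rate([(kin, E)], self.C), rel=1e-14
        )


class TestIsoenzymeKineticsValidation:
    def test_substrate_inhibition_requires_ki(self):
        with pytest.raises(ValueError, match="Ki"):
            IsoenzymeKinetics("Tpi1p", "substrate_inhibition", 564.0, {"DHAP": 6.45})

    def test_hill_exponent_at_least_one(self):
        with pytest.raises(ValueError, match="hill"):
            IsoenzymeKinetics("Pgk1p", "hill_modified", 58.6, {"ADP": 0.2},
                              Keq=3200.0, hill={"ADP": 0.5})

    def test_negative_kcat_rejected(self):
        with pytest.raises(ValueError):
            IsoenzymeKinetics("X", "mm_irreversible", -1.0, {"S": 1.0})

    def test_pgk_hill_adp_squared(self):
        kin = IsoenzymeKinetics("Pgk1p", "hill_modified", 58.6,
                                {"BPG": 0.003, "ADP": 0.2, "P3G": 4.58, "ATP": 1.99},
                                Keq=3200.0, hill={"ADP": 2.0})
        law = kin.bind(0.25, ["BPG", "ADP"], ["P3G", "ATP"])
        lo = law.rate({"BPG": 0.001, "ADP": 0.01, "P3G": 0.0, "ATP": 0.0})
        hi = law.rate({"BPG": 0.001, "ADP": 0.02, "P3G": 0.0, "ATP": 0.0})
        # far below KmADP the quadratic ADP dependence makes doubling ADP
        # nearly quadruple the rate
        assert hi / lo == pytest.approx(4.0, rel=0.02)
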