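"""Reaction parsing, exact balance, transformed Gibbs energies, linear algebra."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syntherm.reactions import (
    Infeasible,
    MissingFormationEnergyError,
    Reaction,
    ReactionParseError,
    ThermoConditions,
    UnderdeterminedError,
    check_balance,
    combine,
    decompose,
    delta_g_actual,
    delta_g_standard_prime,
    parse_reaction,
)

ALL_LABELS = ["r1", "r2", "r3", "r4", "r4.1", "r4.2", "r5", "r6", "r7", "r8", "r9"]

# label -> exact linear combination of component labels (stoichiometric identities)
COMPOSITES = {
    "r4": {"r4.1": 3, "r4.2": 1},
    "r5": {"r4.1": -1, "r4.2": 1},
    "r6": {"r3": 2, "r4.1": 1, "r4.2": 1},
    "r7": {"r3": 1, "r4.2": 1},
    "r8": {"r1": 1, "r7": Fraction(15, 2)},
    "r9": {"r1": 1, "r2": Fraction(15, 4)},
}


class TestParsing:
    def test_desulfonation_has_six_species(self, table):
        r = parse_reaction("C2H5O4S- + H2O -> C2H3O2- + SO3^2- + 2 H+ + H2", table)
        assert len(r.stoich) == 6
        assert r.coefficient("isethionate") == -1
        assert r.coefficient("H+") == 2

    def test_copy_pasted_dialect_matches_canonical(self, table, reactions):
        # unicode arrow/minus, subscript underscores, and the missing-space '+'
        r = parse_reaction("SO_4_^2−^ + 4H_2_ +H^+^ → HS^−^ + 4H_2_O", table)
        assert r == reactions["r5"]

    def test_decimal_coefficients_are_exact(self, table, reactions):
        r = parse_reaction(
            "C18H33O2- + 7.5 C2H5O4S- + H2O -> 16.5 C2H3O2- + 7.5 HS- + 15.5 H+", table
        )
        assert r.coefficient("isethionate") == Fraction(-15, 2)
        assert r == reactions["r8"]

    def test_self_reaction_cancels_with_warning(self, table):
        with pytest.warns(UserWarning, match="cancels"):
            r = parse_reaction("H2O -> H2O", table)
        assert r.is_empty

    def test_missing_arrow_rejected(self, table):
        with pytest.raises(ReactionParseError, match="arrow"):
            parse_reaction("H2 + H2O", table)

    def test_unknown_species_rejected(self, table):
        with pytest.raises(ReactionParseError):
            parse_reaction("glucose -> acetate", table)


class TestBalance:
    @pytest.mark.parametrize("label", ALL_LABELS)
    def test_network_reactions_conserve_everything(self, label, reactions, table):
        rep = check_balance(reactions[label], table)
        assert rep.is_balanced
        assert all(v == 0 for v in rep.element_residuals.values())
        assert rep.charge_residual == 0
        assert rep.electron_residual == 0

    def test_corrupted_coefficient_is_caught_exactly(self, reactions, table):
        stoich = dict(reactions["r1"].stoich)
        stoich["H2"] = Fraction(14)  # true coefficient is 15
        rep = check_balance(Reaction(stoich), table)
        assert not rep.is_balanced
        assert rep.element_residuals["H"] == -2
        assert rep.electron_residual == -2
        assert rep.charge_residual == 0


class TestStandardGibbs:
    @pytest.mark.parametrize(
        "label, tol",
        [("r2", 0.2), ("r4", 0.2), ("r4.1", 0.2), ("r4.2", 0.2), ("r5", 0.2)],
    )
    def test_primitives_from_formation_energies(self, label, tol, reactions, table, ref_dg, cond):
        assert delta_g_standard_prime(reactions[label], table, cond) == pytest.approx(
            ref_dg[label], abs=tol
        )

    def test_empty_reaction_is_zero(self, table, cond):
        assert delta_g_standard_prime(Reaction({}), table, cond) == 0.0

    def test_missing_formation_energy_names_compound(self, table, cond):
        r = Reaction({"BrES": -1, "H2O": -1, "isethionate": 1, "bromide": 1, "H+": 1})
        with pytest.raises(MissingFormationEnergyError, match="BrES"):
            delta_g_standard_prime(r, table, cond)

    def test_ph_enters_only_through_proton_count(self, reactions, table):
        # one proton consumed: dG0' shifts by -RT ln(10) per pH unit
        neutral = delta_g_standard_prime(reactions["r2"], table, ThermoConditions(ph=7))
        acidic = delta_g_standard_prime(reactions["r2"], table, ThermoConditions(ph=6))
        rt_ln10 = 8.314 * 298.15 * math.log(10) / 1000
        assert neutral - acidic == pytest.approx(rt_ln10, abs=1e-9)


class TestActualGibbs:
    def test_unit_activities_reduce_to_standard(self, reactions, table, cond):
        for label in ("r1", "r2", "r7"):
            assert delta_g_actual(reactions[label], table, cond, {"H2": 1.0}) == pytest.approx(
                delta_g_standard_prime(reactions[label], table, cond)
            )

    def test_beta_oxidation_becomes_exergonic_at_low_hydrogen(self, reactions, table, cond):
        # 325.86 + 15*RT*ln(1e-5) = -102.22 kJ (hand-computed closed form)
        dg = delta_g_actual(reactions["r1"], table, cond, {"H2": 1e-5})
        assert dg == pytest.approx(-102.22, abs=0.02)

    def test_methanogenesis_stays_exergonic_at_low_hydrogen(self, reactions, table, cond):
        # dG0'(calc) + 4*RT*ln(1e5) = -21.33 kJ (hand-computed closed form)
        dg = delta_g_actual(reactions["r2"], table, cond, {"H2": 1e-5})
        assert dg == pytest.approx(-21.33, abs=0.02)

    def test_activity_increment_is_closed_form(self, reactions, table, cond):
        base = delta_g_standard_prime(reactions["r2"], table, cond)
        dg = delta_g_actual(reactions["r2"], table, cond, {"H2": 1e-5, "CH4": 0.5})
        expected = base + cond.rt_kj * (-4 * math.log(1e-5) + 1 * math.log(0.5))
        assert dg == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_activity_rejected(self, reactions, table, cond):
        with pytest.raises(ValueError, match="positive"):
            delta_g_actual(reactions["r2"], table, cond, {"H2": 0.0})

    def test_proton_activity_goes_through_ph(self, reactions, table, cond):
        with pytest.raises(ValueError, match="pH|ph"):
            delta_g_actual(reactions["r2"], table, cond, {"H+": 1e-7})


class TestAlgebra:
    @pytest.mark.parametrize("label, parts", COMPOSITES.items())
    def test_composites_are_exact_combinations(self, label, parts, reactions):
        combo = combine([(reactions[l], c) for l, c in parts.items()])
        assert combo == reactions[label]

    @pytest.mark.parametrize("label, parts", COMPOSITES.items())
    def test_reference_energies_are_internally_consistent(self, label, parts, ref_dg):
        # accumulated rounding of 2-d.p. reference values stays within 0.02 kJ
        linear = sum(float(c) * ref_dg[l] for l, c in parts.items())
        assert linear == pytest.approx(ref_dg[label], abs=0.02)

    def test_beta_oxidation_recovered_from_overall(self, reactions, ref_dg):
        # r1 = r9 - 3.75 r2, in both stoichiometry and energy
        back = combine([(reactions["r9"], 1), (reactions["r2"], Fraction(-15, 4))])
        assert back == reactions["r1"]
        assert ref_dg["r9"] - 3.75 * ref_dg["r2"] == pytest.approx(ref_dg["r1"], abs=0.02)

    def test_reaction_minus_itself_is_empty(self, reactions):
        r = reactions["r3"]
        assert combine([(r, 1), (r, -1)]).is_empty

    @pytest.mark.parametrize(
        "target, basis, expected",
        [
            ("r4", ["r4.1", "r4.2"], (Fraction(3), Fraction(1))),
            ("r5", ["r4.1", "r4.2"], (Fraction(-1), Fraction(1))),
            ("r1", ["r1"], (Fraction(1),)),
            ("r8", ["r1", "r3", "r4.2"], (Fraction(1), Fraction(15, 2), Fraction(15, 2))),
        ],
    )
    def test_decompose_exact_solutions(self, target, basis, expected, reactions):
        coeffs = decompose(reactions[target], [reactions[b] for b in basis])
        assert coeffs == expected

    def test_decompose_underdetermined_reports_rank(self, reactions):
        basis = [reactions["r4.1"], reactions["r4.1"].scaled(2)]
        with pytest.raises(UnderdeterminedError) as exc:
            decompose(reactions["r4.1"], basis)
        assert exc.value.rank == 1
        assert exc.value.n_basis == 2

    def test_decompose_infeasible_returns_residual(self, reactions):
        result = decompose(reactions["r2"], [reactions["r4.1"]])
        assert isinstance(result, Infeasible)
        assert not result
        assert result.residual  # nonzero exact residual

    coeff_strategy = st.lists(
        st.fractions(min_value=-5, max_value=5, max_denominator=8), min_size=5, max_size=5
    )

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(coeffs=coeff_strategy)
    def test_gibbs_energy_is_linear_under_combination(self, coeffs, network, cond):
        rxns = [network.reactions[l] for l in ("r1", "r2", "r3", "r4.1", "r4.2")]
        combo = combine(list(zip(rxns, coeffs)))
        expected = sum(
            float(c) * delta_g_standard_prime(r, network.table, cond)
            for r, c in zip(rxns, coeffs)
        )
        actual = delta_g_standard_prime(combo, network.table, cond)
        assert actual == pytest.approx(expected, abs=1e-8)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(coeffs=coeff_strategy)
    def test_decompose_inverts_combine_on_full_rank_basis(self, coeffs, network):
        basis = [network.reactions[l] for l in ("r1", "r2", "r3", "r4.1", "r4.2")]
        target = combine(list(zip(basis, coeffs)))
        recovered = decompose(target, basis)
        assert tuple(recovered) == tuple(Fraction(c) for c in coeffs)
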