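from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ironmat import (
    FluxMode,
    YieldPoint,
    apply_regulatory_rules,
    brute_force_extreme_rays,
    enumerate_efms,
    limitation_optima,
    mode_yields,
)
from ironmat.efm import EFMBudgetError, parse_rule, _eval_rule
from ironmat.network import MetabolicNetwork, Metabolite, Reaction, stoichiometric_matrix
from ironmat.synth import ToyNetworkSpec, make_toy_network


def _mode_set(modes):
    return {tuple(sorted(m.normalized().flux.items())) for m in modes}


class TestEnumeration:
    @pytest.mark.parametrize(
        "kind,size,count",
        [("chain", 3, 1), ("diamond", 6, 2), ("parallel_k", 3, 3), ("parallel_k", 5, 5)],
    )
    def test_known_mode_counts(self, kind, size, count):
        net = make_toy_network(ToyNetworkSpec(kind=kind, size=size))
        assert len(enumerate_efms(net)) == count

    def test_reversible_middle_reaction_no_spurious_cycle(self):
        mets = [Metabolite("Aext", is_external=True), Metabolite("A"),
                Metabolite("B"), Metabolite("Bext", is_external=True)]
        rxns = [Reaction("Rin", {"Aext": -1, "A": 1}, is_exchange=True),
                Reaction("Rmid", {"A": -1, "B": 1}, reversible=True),
                Reaction("Rout", {"B": -1, "Bext": 1}, is_exchange=True)]
        net = MetabolicNetwork(mets, rxns, "Rmid")
        modes = enumerate_efms(net)
        assert len(modes) == 1
        assert modes[0].flux["Rmid"] > 0  # forward only; the 2-cycle is discarded

    def test_fully_reversible_chain_gives_both_directions(self):
        mets = [Metabolite("Aext", is_external=True), Metabolite("A"),
                Metabolite("Bext", is_external=True)]
        rxns = [Reaction("Rin", {"Aext": -1, "A": 1}, reversible=True, is_exchange=True),
                Reaction("Rout", {"A": -1, "Bext": 1}, reversible=True, is_exchange=True)]
        net = MetabolicNetwork(mets, rxns, "Rout")
        assert len(enumerate_efms(net)) == 2

    def test_budget_exceeded_raises(self):
        net = make_toy_network(ToyNetworkSpec(kind="parallel_k", size=6))
        with pytest.raises(EFMBudgetError):
            enumerate_efms(net, budget=3)

    def test_deterministic_ordering(self, autotroph_net):
        a = enumerate_efms(autotroph_net)
        b = enumerate_efms(autotroph_net)
        assert [m.flux for m in a] == [m.flux for m in b]


class TestModeInvariants:
    """Every returned mode satisfies S v = 0 exactly, sign constraints and
    pairwise support minimality."""

    @pytest.mark.parametrize("spec", [
        ToyNetworkSpec(kind="chain"),
        ToyNetworkSpec(kind="diamond"),
        ToyNetworkSpec(kind="parallel_k", size=4),
        ToyNetworkSpec(kind="autotroph_fixture"),
        ToyNetworkSpec(kind="heterotroph_fixture"),
        ToyNetworkSpec(kind="random", size=8, seed=3),
        ToyNetworkSpec(kind="random", size=10, seed=4),
    ])
    def test_exact_steady_state_and_minimality(self, spec):
        net = make_toy_network(spec)
        modes = enumerate_efms(net)
        assert modes, "every toy network must have at least one mode"
        S = stoichiometric_matrix(net, internal_only=True)
        irreversible = {r.id for r in net.reactions if not r.reversible}
        for m in modes:
            for mid in S.index:
                total = sum(
                    S.at[mid, rid] * v for rid, v in m.flux.items()
                )
                assert total == 0  # exact rational arithmetic
            for rid in m.support & irreversible:
                assert m.flux[rid] > 0
        supports = [m.support for m in modes]
        for i, si in enumerate(supports):
            for j, sj in enumerate(supports):
                assert i == j or not si < sj


class TestOracleEquivalence:
    @pytest.mark.parametrize("spec", [
        ToyNetworkSpec(kind="chain"),
        ToyNetworkSpec(kind="diamond"),
        ToyNetworkSpec(kind="parallel_k", size=3),
        ToyNetworkSpec(kind="random", size=8, seed=0),
        ToyNetworkSpec(kind="random", size=10, seed=1),
        ToyNetworkSpec(kind="random", size=12, seed=2),
    ])
    def test_enumerator_matches_brute_force(self, spec):
        net = make_toy_network(spec)
        assert _mode_set(enumerate_efms(net)) == _mode_set(brute_force_extreme_rays(net))

    def test_rational_kernel_agrees_with_sympy(self):
        """Independent check of the exact linear algebra behind both routes."""
        import sympy

        net = make_toy_network(ToyNetworkSpec(kind="random", size=9, seed=7))
        S = stoichiometric_matrix(net, internal_only=True)
        rows = [list(S.loc[m]) for m in S.index]
        from ironmat._rational import nullspace, rank

        M = sympy.Matrix([[sympy.Rational(x) for x in row] for row in rows])
        assert rank(rows) == M.rank()
        assert len(nullspace(rows)) == len(M.nullspace())

    def test_brute_force_size_guard(self):
        net = make_toy_network(ToyNetworkSpec(kind="parallel_k", size=20))
        with pytest.raises(ValueError, match="guard"):
            brute_force_extreme_rays(net, max_split_columns=16)


class TestRegulatoryRules:
    def test_forbidden_pair_removed(self, diamond):
        modes = enumerate_efms(diamond)
        kept = apply_regulatory_rules(modes, ["NOT (Rup AND Rup2)"])
        assert len(kept) == 1
        assert "Rup" not in kept[0].support

    def test_empty_rule_list_is_identity(self, diamond):
        modes = enumerate_efms(diamond)
        assert apply_regulatory_rules(modes, []) == modes

    def test_unknown_reaction_in_rule_rejected(self, diamond):
        modes = enumerate_efms(diamond)
        with pytest.raises(ValueError, match="R999"):
            apply_regulatory_rules(modes, ["R999"], known_reactions=set(diamond.reaction_ids))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(["Rin", "Rup", "Rdown", "Rup2", "Rdown2", "Rout"]),
                    min_size=1, max_size=3, unique=True),
           st.sampled_from(["AND", "OR"]), st.booleans())
    def test_agrees_with_direct_boolean_evaluation(self, lits, op, negate):
        """Pruning matches evaluating the rule as a plain Python expression."""
        net = make_toy_network(ToyNetworkSpec(kind="diamond"))
        modes = enumerate_efms(net)
        rule = f" {op} ".join(lits)
        if negate:
            rule = f"NOT ({rule})"
        kept = apply_regulatory_rules(modes, [rule])
        pyop = " and " if op == "AND" else " or "
        for m in modes:
            expected = eval(  # independent evaluator on Python booleans
                ("not (" if negate else "(")
                + pyop.join(str(lit in m.support) for lit in lits)
                + ")"
            )
            assert (m in kept) == expected

    def test_subset_and_idempotent(self, diamond):
        modes = enumerate_efms(diamond)
        rules = ["NOT Rup OR Rout"]
        once = apply_regulatory_rules(modes, rules)
        assert set(id(m) for m in once) <= set(id(m) for m in modes)
        assert apply_regulatory_rules(once, rules) == once

    def test_parser_handles_nesting(self):
        node = parse_rule("NOT (A AND (B OR NOT C))")
        assert _eval_rule(node, frozenset({"C"}))
        assert not _eval_rule(node, frozenset({"A", "B"}))


class TestYields:
    def test_fe_fixture_lands_at_table_scale(self, autotroph_net):
        """The donor:O2:biomass stoichiometry 152:38:1 per Cmole."""
        modes = enumerate_efms(autotroph_net)
        points, skipped = mode_yields(
            modes, "BIOMASS", 1.0, {"Fe2": "EX_fe2"}, "EX_o2"
        )
        assert skipped == 0
        (pt,) = points
        assert pt.donor_per_cmol_biomass == pytest.approx(152.0)
        assert pt.o2_per_cmol_biomass == pytest.approx(38.0)

    def test_modes_without_biomass_flux_skipped(self, autotroph_net):
        modes = enumerate_efms(autotroph_net)
        silent = FluxMode({"EX_fe2": Fraction(4), "EX_o2": Fraction(1),
                           "ETC": Fraction(1)})
        points, skipped = mode_yields(
            modes + [silent], "BIOMASS", 1.0, {"Fe2": "EX_fe2"}, "EX_o2"
        )
        assert skipped == 1
        assert len(points) == len(modes)

    def test_scale_invariance(self, autotroph_net):
        modes = enumerate_efms(autotroph_net)
        doubled = [FluxMode({r: 2 * v for r, v in m.flux.items()}) for m in modes]
        a, _ = mode_yields(modes, "BIOMASS", 1.0, {"Fe2": "EX_fe2"}, "EX_o2")
        b, _ = mode_yields(doubled, "BIOMASS", 1.0, {"Fe2": "EX_fe2"}, "EX_o2")
        assert [(p.donor_per_cmol_biomass, p.o2_per_cmol_biomass) for p in a] == [
            (p.donor_per_cmol_biomass, p.o2_per_cmol_biomass) for p in b
        ]


class TestLimitationOptima:
    POINTS = [
        YieldPoint("biomass", 2.4, 1.30, 0),
        YieldPoint("biomass", 3.8, 1.23, 1),
    ]

    def test_carbon_vs_oxygen_optimum(self):
        assert limitation_optima(self.POINTS, "carbon").mode_id == 0
        assert limitation_optima(self.POINTS, "oxygen").mode_id == 1

    def test_single_point_returned(self):
        assert limitation_optima(self.POINTS[:1], "oxygen") is self.POINTS[0]

    def test_tie_break_by_mode_id(self):
        dup = [YieldPoint("d", 1.0, 1.0, 5), YieldPoint("d", 1.0, 1.0, 2)]
        assert limitation_optima(dup, "carbon").mode_id == 2

    def test_empty_list_error(self):
        with pytest.raises(ValueError):
            limitation_optima([], "carbon")
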