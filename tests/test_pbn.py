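"""Probabilistic rule-set generation: probabilities, structure, invariants."""

import itertools
import math

import pytest
import sympy
from hypothesis import given, settings, strategies as st

import rxnpbn as rp
from rxnpbn.core import parse_network
from rxnpbn.expressions import FALSE, equivalent, land, lit, lnot, lor
from rxnpbn.io import write_boolnet
from rxnpbn.pbn import (
    PBNParams,
    assign_probabilities,
    build_pbn,
    build_quantitative_rules,
    exact_probabilities,
)


class TestAssignProbabilities:
    def test_two_modifier_worked_values(self):
        probs = assign_probabilities(2, PBNParams(p_false=0.1, k_base=10.0))
        assert probs == [0.008108, 0.08108, 0.810812, 0.1]

    def test_zero_modifier_values(self):
        assert assign_probabilities(0, PBNParams(p_false=0.1, k_base=10.0)) == [0.9, 0.1]

    def test_unit_k_gives_equal_shares(self):
        probs = assign_probabilities(2, PBNParams(p_false=0.1, k_base=1.0))
        assert probs == pytest.approx([0.3, 0.3, 0.3, 0.1], abs=1e-9)

    def test_exact_values_follow_geometric_law(self):
        params = PBNParams(p_false=0.1, k_base=10.0)
        exact = exact_probabilities(2, params)
        p0 = 0.9 / (1 + 10 + 100)
        assert exact == pytest.approx([p0, 10 * p0, 100 * p0, 0.1], rel=1e-12)

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            assign_probabilities(-1, PBNParams())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PBNParams(p_false=1.0)
        with pytest.raises(ValueError):
            PBNParams(k_base=0.0)

    def test_small_k_warns_about_inverted_preference(self):
        with pytest.warns(UserWarning, match="inverts"):
            PBNParams(p_false=0.1, k_base=0.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n=st.integers(0, 8),
        k=st.floats(1.0, 1e4),
        p_false=st.floats(0.0, 0.99),
    )
    def test_normalization_property(self, n, k, p_false):
        """Exact and reported probabilities both sum to 1, all >= 0."""
        params = PBNParams(p_false=p_false, k_base=k)
        exact = exact_probabilities(n, params)
        reported = assign_probabilities(n, params)
        assert len(exact) == len(reported) == n + 2
        assert math.isclose(sum(exact), 1.0, abs_tol=1e-9)
        assert math.isclose(sum(reported), 1.0, abs_tol=1e-9)
        assert all(p >= 0 for p in exact)
        assert all(p >= -1e-12 for p in reported)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(1, 6), p_false=st.floats(0.0, 0.9))
    def test_strictly_increasing_for_k_above_one(self, n, p_false):
        exact = exact_probabilities(n, PBNParams(p_false=p_false, k_base=10.0))
        non_false = exact[:-1]
        if p_false < 0.9:  # degenerate mass aside
            assert all(b > a for a, b in zip(non_false, non_false[1:]))

    def test_large_k_concentrates_mass_on_most_restrictive(self):
        exact = exact_probabilities(3, PBNParams(p_false=0.1, k_base=1e6))
        assert exact[3] == pytest.approx(0.9, rel=1e-5)
        assert sum(exact[:3]) < 1e-5


class TestQuantitativeRules:
    def test_worked_example_rule_structure(self, worked_network):
        rs = build_quantitative_rules(
            worked_network, "A_ppi_B", PBNParams(p_false=0.1, k_base=10.0)
        )
        exprs = [e for e, _ in rs.rules]
        base = land(lit("A"), lit("B"))
        assert equivalent(exprs[0], base)
        assert equivalent(exprs[1], land(base, lor(lit("B--C"), lnot(lit("A--D")))))
        assert equivalent(exprs[2], land(base, lit("B--C"), lnot(lit("A--D"))))
        assert exprs[3] is FALSE
        assert rs.reported() == [0.008108, 0.08108, 0.810812, 0.1]

    def test_worked_example_equivalence_against_sympy(self, worked_network):
        """Independent route: the generated formulas match the printed ones
        under sympy's logical equivalence."""
        rs = build_quantitative_rules(
            worked_network, "A_ppi_B", PBNParams(p_false=0.1, k_base=10.0)
        )
        a, b, bc, ad = sympy.symbols("a b bc ad")
        printed = [
            a & b,
            a & b & (bc | ~ad),
            a & b & (bc & ~ad),
        ]
        table = {"A": a, "B": b, "B--C": bc, "A--D": ad}

        def to_sympy(expr):
            from rxnpbn import expressions as ex

            if expr is ex.TRUE:
                return sympy.true
            if expr is ex.FALSE:
                return sympy.false
            if isinstance(expr, ex.Lit):
                return table[expr.name]
            if isinstance(expr, ex.Not):
                return ~to_sympy(expr.operand)
            if isinstance(expr, ex.And):
                return sympy.And(*(to_sympy(o) for o in expr.operands))
            return sympy.Or(*(to_sympy(o) for o in expr.operands))

        for mine, ref in zip([e for e, _ in rs.rules[:3]], printed):
            assert sympy.simplify_logic(sympy.Equivalent(to_sympy(mine), ref)) == sympy.true

    @pytest.mark.parametrize("n", range(7))
    def test_rule_count_is_n_plus_two(self, n):
        """A reaction with n quantitative modifiers gets n + 2 rules."""
        lines = [f"A{i}_ppi_B{i}" for i in range(n)]
        conts = "".join(f"; K+ A{i}--B{i}" for i in range(n))
        net = parse_network("\n".join(lines + [f"X_ppi_Y{conts}"]) + "\n")
        rs = build_quantitative_rules(net, "X_ppi_Y", PBNParams())
        assert len(rs.rules) == n + 2

    @pytest.mark.parametrize("n", range(1, 6))
    def test_monotone_stringency_exhaustive(self, n):
        """f_i TRUE implies f_{i-1} TRUE, for every assignment."""
        lines = [f"A{i}_ppi_B{i}" for i in range(n)]
        signs = ["K+" if i % 2 == 0 else "K-" for i in range(n)]
        conts = "".join(f"; {s} A{i}--B{i}" for i, s in enumerate(signs))
        net = parse_network("\n".join(lines + [f"X_ppi_Y{conts}"]) + "\n")
        rs = build_quantitative_rules(net, "X_ppi_Y", PBNParams())
        exprs = [e for e, _ in rs.rules[:-1]]
        names = sorted(frozenset().union(*(e.literals() for e in exprs)))
        for bits in itertools.product((False, True), repeat=len(names)):
            env = dict(zip(names, bits))
            values = [e.evaluate(env) for e in exprs]
            for i in range(1, len(values)):
                assert not values[i] or values[i - 1]

    def test_complex_case_structure(self):
        """One !, two K+, two K-, one x: six rules; every non-false rule
        carries the absolutes; f_i needs >= i fulfilled modifiers."""
        net = parse_network(
            "P1_ppi_Q1\nP2_ppi_Q2\nP3_ppi_Q3\nP4_ppi_Q4\nP5_ppi_Q5\nP6_ppi_Q6\n"
            "R_ppi_S; ! P1--Q1; K+ P2--Q2; K+ P3--Q3; K- P4--Q4; K- P5--Q5; x P6--Q6\n"
        )
        rs = build_quantitative_rules(net, "R_ppi_S", PBNParams())
        assert len(rs.rules) == 6  # f0..f4 + FALSE
        mods = [("P2--Q2", True), ("P3--Q3", True), ("P4--Q4", False), ("P5--Q5", False)]
        for i, (expr, _) in enumerate(rs.rules[:-1]):
            # absolutes present in every non-false rule
            absent = expr.evaluate(
                {"R": True, "S": True, "P1--Q1": False, "P6--Q6": False,
                 **{m: v for m, v in mods}}
            )
            assert not absent
            forbidden = expr.evaluate(
                {"R": True, "S": True, "P1--Q1": True, "P6--Q6": True,
                 **{m: v for m, v in mods}}
            )
            assert not forbidden
            # with absolutes satisfied, f_i needs >= i fulfilled modifiers
            for fulfilled in range(5):
                env = {"R": True, "S": True, "P1--Q1": True, "P6--Q6": False}
                for j, (name, wants_true) in enumerate(mods):
                    met = j < fulfilled
                    env[name] = wants_true if met else not wants_true
                assert expr.evaluate(env) == (fulfilled >= i)

    def test_no_contingency_reaction_still_gets_false_rule(self, worked_pbn):
        rules = worked_pbn.rules["A_ppi_D"]
        assert len(rules) == 2
        assert rules[1][0] is FALSE
        assert rules[0][1] == pytest.approx(0.9)


class TestBuildPBN:
    def test_state_nodes_keep_single_deterministic_rule(self, worked_pbn):
        for node in worked_pbn.state_nodes:
            assert len(worked_pbn.rules[node]) == 1
            assert worked_pbn.rules[node][0][1] == 1.0

    def test_boolnet_export_matches_printed_block(self, worked_pbn):
        text, names = write_boolnet(worked_pbn)
        lines = text.splitlines()
        assert lines[0] == "targets, factors, probabilities"
        reaction_lines = [
            l for l in lines if l.split(",")[0] in ("B_ppi_C", "A_ppi_D", "A_ppi_B")
        ]
        assert len(reaction_lines) == 8
        assert "A_ppi_B, A & B, 0.008108" in lines
        assert "A_ppi_B, A & B & (B_C | !A_D), 0.08108" in lines
        assert "A_ppi_B, A & B & B_C & !A_D, 0.810812" in lines
        assert "A_ppi_B, 0, 0.1" in lines
        assert "A_ppi_D, A & D, 0.9" in lines
        assert "B_ppi_C, B & C, 0.9" in lines

    def test_degenerate_params_reduce_to_qualitative_model(self):
        net = parse_network("B_ppi_C\nA_ppi_B; ! B--C\n")
        pbn = build_pbn(net, PBNParams(p_false=0.0, k_base=10.0))
        qual = rp.build_model(net)
        for node in pbn.reaction_nodes:
            effective = [(e, p) for e, p in pbn.rules[node] if p > 0]
            assert len(effective) == 1
            assert equivalent(effective[0][0], qual.single_rule(node))

    def test_override_false_rule_renormalizes(self, worked_network):
        pbn = build_pbn(
            worked_network,
            PBNParams(p_false=0.1, k_base=10.0),
            overrides={"A_ppi_B": {3: 0.0}},
        )
        probs = [p for _, p in pbn.rules["A_ppi_B"]]
        assert probs[3] == 0.0
        assert sum(probs) == pytest.approx(1.0, abs=1e-9)
        # remaining mass scaled proportionally
        exact = exact_probabilities(2, PBNParams(p_false=0.1, k_base=10.0))
        scale = 1.0 / (1.0 - 0.1)
        assert probs[:3] == pytest.approx([p * scale for p in exact[:3]])

    def test_override_not_summing_to_one_rejected(self, worked_network):
        with pytest.raises(ValueError, match="sum to 1.8|exceed"):
            build_pbn(
                worked_network,
                PBNParams(p_false=0.1, k_base=10.0),
                overrides={"A_ppi_D": {0: 0.9, 1: 0.9}},
            )

    def test_inert_contingencies_leave_rule_sets_unchanged(self):
        base = parse_network("B_ppi_C\nA_ppi_D\nA_ppi_B; K+ B--C\n")
        inert = parse_network("B_ppi_C\nA_ppi_D\nA_ppi_B; K+ B--C; 0 A--D; ? A--B\n")
        params = PBNParams(p_false=0.1, k_base=10.0)
        assert build_pbn(base, params).rules == build_pbn(inert, params).rules


class TestQualitativeLimit:
    def test_high_k_trajectory_matches_strengthened_qualitative_model(self, hog_network):
        """p_false = 0 and a huge k reproduce the absolute-contingency
        dynamics almost everywhere (>= 99.9% of node-steps)."""
        quant = rp.weaken_contingencies(hog_network)
        pbn = build_pbn(quant, PBNParams(p_false=0.0, k_base=1e6))
        qual = rp.build_model(rp.strengthen_contingencies(quant))
        cfg = rp.SimulationConfig(steps=280, seed=5)
        t_pbn = rp.run(pbn, cfg)
        t_qual = rp.run(qual, cfg)
        assert pbn.nodes == qual.nodes
        agreement = (t_pbn == t_qual).mean()
        assert agreement >= 0.999
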