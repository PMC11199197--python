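"""GPR parsing, evaluation, network transformation, disabling sets."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from gemcuts.config import BudgetExceededError
from gemcuts.gpr import (
    GPRParseError,
    evaluate_gpr,
    gpr_genes,
    gpr_operator_count,
    gpr_stats,
    gpr_to_network,
    gpr_to_string,
    minimal_disabling_sets,
    network_sink_feasible,
    parse_gpr,
)

from conftest import chain_model, disabling_sets_oracle

GENES = [f"g{i}" for i in range(1, 6)]


def _rules(max_leaves=8):
    base = st.sampled_from(GENES)
    def extend(children):
        return st.tuples(st.sampled_from([" and ", " or "]),
                         st.lists(children, min_size=2, max_size=3)).map(
            lambda t: "(" + t[0].join(t[1]) + ")")
    return st.recursive(base, extend, max_leaves=max_leaves)


class TestParse:
    def test_precedence_and_shape(self):
        e = parse_gpr("g1 and (g2 or g3)")
        assert e.kind == "AND"
        kinds = sorted(ch.kind for ch in e.children)
        assert kinds == ["GENE", "OR"]

    def test_and_binds_tighter_than_or(self):
        e = parse_gpr("g1 and g2 or g3")
        assert e.kind == "OR"
        # falsified only by {g3 plus one of g1,g2}
        assert not evaluate_gpr(e, {"g3", "g1"})
        assert evaluate_gpr(e, {"g1", "g2"})

    def test_empty_rule_is_no_rule(self):
        assert parse_gpr("") is None
        assert parse_gpr("   ") is None
        assert parse_gpr(None) is None

    def test_same_operator_flattened(self):
        e = parse_gpr("g1 and (g2 and (g3 and g4))")
        assert e.kind == "AND" and len(e.children) == 4

    def test_case_insensitive_operators(self):
        e = parse_gpr("g1 AND g2 Or g3")
        assert e.kind == "OR"

    @pytest.mark.parametrize("bad", [
        "(g1 and", "g1 or", "g1 g2", "and g1", "g1 and )", "(", ")",
        "g1 and or g2",
    ])
    def test_grammar_violations_carry_position(self, bad):
        with pytest.raises(GPRParseError) as exc:
            parse_gpr(bad)
        assert exc.value.position >= 0

    def test_thousands_of_literals_no_recursion_blowup(self):
        wide = " or ".join(f"g{i}" for i in range(3000))
        assert len(parse_gpr(wide).children) == 3000
        deep = "(" * 1500 + "g1 and g2" + ")" * 1500
        assert parse_gpr(deep).kind == "AND"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(_rules())
    def test_serialize_reparse_truth_table_identical(self, rule):
        e1 = parse_gpr(rule)
        e2 = parse_gpr(gpr_to_string(e1))
        genes = sorted(gpr_genes(e1))
        assert gpr_genes(e2) == gpr_genes(e1)
        for k in range(len(genes) + 1):
            for combo in itertools.combinations(genes, k):
                assert evaluate_gpr(e1, combo) == evaluate_gpr(e2, combo)


class TestEvaluate:
    def test_and_or_semantics(self):
        a = parse_gpr("g1 and g2")
        o = parse_gpr("g1 or g2")
        assert not evaluate_gpr(a, {"g1"})
        assert evaluate_gpr(o, {"g1"})
        assert not evaluate_gpr(o, {"g1", "g2"})

    def test_no_knockout_always_true(self):
        for rule in ("g1", "g1 and g2", "(g1 or g2) and g3"):
            assert evaluate_gpr(parse_gpr(rule), set())

    def test_no_rule_always_true(self):
        assert evaluate_gpr(None, {"g1"})


class TestStats:
    def test_counts_on_simple_rule(self):
        e = parse_gpr("g1 and (g2 or g3)")
        assert len(gpr_genes(e)) == 3
        assert gpr_operator_count(e) == 2

    def test_duplicate_occurrences_counted_in_operators_not_genes(self):
        e = parse_gpr("(g1 and g2) or (g1 and g3)")
        assert len(gpr_genes(e)) == 3
        assert gpr_operator_count(e) == 3

    def test_model_level_maxima(self):
        stats = gpr_stats(chain_model(3))
        assert stats["max_genes"] == 1
        assert stats["n_genes"] == 3
        by_rxn = {r: (g, o) for r, g, o in stats["per_reaction"]}
        assert by_rxn["BIOMASS"] == (0, 0)
        assert by_rxn["R1"] == (1, 0)


class TestNetwork:
    def test_single_gene(self):
        net = gpr_to_network(parse_gpr("g1"))
        assert set(net.gene_inputs) == {"g1"}
        assert network_sink_feasible(net, set())
        assert not network_sink_feasible(net, {"g1"})

    def test_and_blocked_by_either_subunit(self):
        net = gpr_to_network(parse_gpr("g1 and g2"))
        assert network_sink_feasible(net, set())
        assert not network_sink_feasible(net, {"g1"})
        assert not network_sink_feasible(net, {"g2"})

    def test_shared_gene_single_input_reaction(self):
        net = gpr_to_network(parse_gpr("(g1 and g2) or (g1 and g3)"))
        assert len(net.gene_inputs) == 3
        assert not network_sink_feasible(net, {"g1"})

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(_rules(max_leaves=5))
    def test_sink_feasibility_equals_truth_table(self, rule):
        expr = parse_gpr(rule)
        net = gpr_to_network(expr)
        genes = sorted(gpr_genes(expr))
        for k in range(len(genes) + 1):
            for combo in itertools.combinations(genes, k):
                assert network_sink_feasible(net, combo) == \
                    evaluate_gpr(expr, combo)


class TestMinimalDisablingSets:
    @pytest.mark.parametrize("rule,expected", [
        ("g1 and g2", [{"g1"}, {"g2"}]),
        ("g1 or g2", [{"g1", "g2"}]),
        ("(g1 and g2) or (g1 and g3)", [{"g1"}, {"g2", "g3"}]),
    ])
    def test_known_rules(self, rule, expected):
        got = minimal_disabling_sets(parse_gpr(rule))
        assert got == [frozenset(s) for s in expected]

    def test_no_rule_has_no_disabling_sets(self):
        assert minimal_disabling_sets(None) == []

    def test_max_size_truncates_but_stays_complete_below(self):
        got = minimal_disabling_sets(parse_gpr("g1 or g2 or g3"), max_size=2)
        assert got == []
        got = minimal_disabling_sets(parse_gpr("g1 or g2 or g3"), max_size=3)
        assert got == [frozenset({"g1", "g2", "g3"})]

    def test_budget_exceeded_raises_with_reaction_name(self):
        rule = parse_gpr(" or ".join(f"g{i}" for i in range(10)))
        with pytest.raises(BudgetExceededError, match="R_big"):
            minimal_disabling_sets(rule, reaction_id="R_big", budget=5)

    def test_milp_route_matches_brute_force(self):
        # force the artificial-network MILP path with a tiny gene limit
        rule = parse_gpr("(g1 and g2) or (g1 and g3) or g4")
        bf = minimal_disabling_sets(rule)
        via_milp = minimal_disabling_sets(rule, bf_gene_limit=2)
        assert via_milp == bf

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(_rules())
    def test_equals_powerset_oracle_and_is_antichain(self, rule):
        expr = parse_gpr(rule)
        got = minimal_disabling_sets(expr)
        assert got == disabling_sets_oracle(expr)
        for a in got:
            for b in got:
                assert a == b or not a <= b
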