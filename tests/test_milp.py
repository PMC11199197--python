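"""The dual MILP: contract, target restriction, threshold monotonicity."""

import itertools

import pytest

from gemcuts import (
    GemcutsError,
    apply_target_kos,
    build_g_matrix,
    build_gmcs_milp,
    build_mcs_milp,
    enumerate_cut_sets,
    verify_cut_set,
)
from gemcuts.milp import MILPOptions

from conftest import CAP, build_model, chain_model


def isoenzyme_model():
    return build_model([
        ("EX_A", {"A": -1.0}, -10.0, CAP, ""),
        ("R1a", {"A": -1.0, "B": 1.0}, 0.0, CAP, "g1"),
        ("R1b", {"A": -1.0, "B": 1.0}, 0.0, CAP, "g2"),
        ("BIOMASS", {"B": -1.0}, 0.0, CAP, ""),
    ])


def _enumerate(model, g=None, options=None, **kw):
    if g is None:
        g = build_g_matrix(model, 3)
    spec = build_gmcs_milp(model, g, options)
    return spec, enumerate_cut_sets(spec, model, g, **kw)


class TestGeneMILP:
    def test_chain_optimum_one_with_both_supports(self, chain):
        spec, res = _enumerate(chain, max_length=1)
        assert [sorted(r.members) for r in res] == [["g1"], ["g2"], ["g3"]]
        assert all(r.objective == pytest.approx(1.0) for r in res)

    def test_isoenzyme_pair_needs_both_genes(self):
        spec, res = _enumerate(isoenzyme_model(), max_length=2)
        assert [sorted(r.members) for r in res] == [["g1", "g2"]]
        assert res[0].objective == pytest.approx(2.0)

    def test_spontaneous_biomass_path_has_no_gene_cut_sets(self):
        # biomass reachable through no-GPR reactions; the only gene sits
        # on a side branch, so no knockout can block growth
        m = build_model([
            ("EX_A", {"A": -1.0}, -10.0, CAP, ""),
            ("R0", {"A": -1.0, "B": 1.0}, 0.0, CAP, ""),
            ("SIDE", {"A": -1.0, "C": 1.0}, 0.0, CAP, "g1"),
            ("SK_C", {"C": -1.0}, 0.0, CAP, ""),
            ("BIOMASS", {"B": -1.0}, 0.0, CAP, ""),
        ])
        spec, res = _enumerate(m, max_length=3)
        assert list(res) == []

    def test_zero_row_g_matrix_rejected(self, chain):
        g = build_g_matrix(chain, 3)
        g.row_sets, g.matrix = [], g.matrix[:0]
        with pytest.raises(GemcutsError, match="no rows"):
            build_gmcs_milp(chain, g)

    def test_unbounded_biomass_rejected(self, chain):
        j = chain.reaction_index("BIOMASS")
        for rid in chain.reactions:
            k = chain.reaction_index(rid)
            chain.ub[k] = float("inf")
            chain.lb[k] = min(chain.lb[k], 0.0)
        chain.lb[chain.reaction_index("EX_M0")] = float("-inf")
        g = build_g_matrix(chain, 3)
        with pytest.raises(GemcutsError, match="unbounded"):
            build_gmcs_milp(chain, g)


class TestReactionMILP:
    def test_chain_gives_three_singleton_reaction_cuts(self, chain):
        spec = build_mcs_milp(chain)
        res = enumerate_cut_sets(spec, chain, spec.gmatrix, max_length=1)
        assert [sorted(r.members) for r in res] == [["R1"], ["R2"], ["R3"]]
        assert all(r.kind == "reaction" for r in res)

    def test_parallel_paths_need_a_pair(self):
        m = isoenzyme_model()
        spec = build_mcs_milp(m)
        res = enumerate_cut_sets(spec, m, spec.gmatrix, max_length=2)
        assert [sorted(r.members) for r in res] == [["R1a", "R1b"]]

    def test_exchanges_and_biomass_not_knockable_by_default(self, chain):
        spec = build_mcs_milp(chain)
        assert set(spec.y_index) == {"R1", "R2", "R3"}

    def test_restricted_knockable_set(self, chain):
        spec = build_mcs_milp(chain, MILPOptions(knockable=["R2"]))
        res = enumerate_cut_sets(spec, chain, spec.gmatrix, max_length=2)
        assert [sorted(r.members) for r in res] == [["R2"]]

    def test_empty_knockable_set_rejected(self, chain):
        with pytest.raises(ValueError, match="empty"):
            build_mcs_milp(chain, MILPOptions(knockable=[]))


class TestTargetKOs:
    def test_full_gene_set_is_identity(self, chain):
        g = build_g_matrix(chain, 3)
        spec = build_gmcs_milp(chain, g)
        spec = apply_target_kos(spec, g, chain.genes)
        res = enumerate_cut_sets(spec, chain, g, max_length=1)
        assert len(res) == 3

    def test_restriction_to_one_gene(self, chain):
        g = build_g_matrix(chain, 3)
        spec = apply_target_kos(build_gmcs_milp(chain, g), g, {"g1"})
        res = enumerate_cut_sets(spec, chain, g, max_length=3)
        assert [sorted(r.members) for r in res] == [["g1"]]

    def test_excluding_every_row_gives_no_solutions(self):
        m = isoenzyme_model()
        g = build_g_matrix(m, 3)
        spec = apply_target_kos(build_gmcs_milp(m, g), g, {"g1"})
        res = enumerate_cut_sets(spec, m, g, max_length=3)
        assert list(res) == []

    def test_unknown_gene_listed_in_error(self, chain):
        g = build_g_matrix(chain, 3)
        spec = build_gmcs_milp(chain, g)
        with pytest.raises(ValueError, match="gX"):
            apply_target_kos(spec, g, {"g1", "gX"})


class TestThresholdMonotonicity:
    def test_raising_b_enlarges_the_lethal_family(self):
        # capacities 3 and 4: knocking one branch leaves 4 or 3 units
        m = build_model([
            ("EX_A1", {"A1": -1.0}, -3.0, CAP, ""),
            ("EX_A2", {"A2": -1.0}, -4.0, CAP, ""),
            ("R1", {"A1": -1.0, "B": 1.0}, 0.0, CAP, "g1"),
            ("R2", {"A2": -1.0, "B": 1.0}, 0.0, CAP, "g2"),
            ("BIOMASS", {"B": -1.0}, 0.0, CAP, ""),
        ])
        lo, hi = 1.0, 5.0
        lethal = {b: {frozenset(c)
                      for k in range(1, 3)
                      for c in itertools.combinations(["g1", "g2"], k)
                      if verify_cut_set(m, frozenset(c), b)}
                  for b in (lo, hi)}
        assert lethal[lo] <= lethal[hi]
        assert lethal[lo] == {frozenset({"g1", "g2"})}
        assert frozenset({"g1"}) in lethal[hi]
        # the MILP sees the same growth: singletons appear only at high b
        g = build_g_matrix(m, 2)
        _, res_lo = _enumerate(m, g, MILPOptions(b=lo), max_length=2)
        _, res_hi = _enumerate(m, g, MILPOptions(b=hi), max_length=2)
        assert [sorted(r.members) for r in res_lo] == [["g1", "g2"]]
        assert [sorted(r.members) for r in res_hi] == [["g1"], ["g2"]]


class TestSpecObject:
    def test_binary_count_and_lp_dump(self, chain):
        g = build_g_matrix(chain, 3)
        spec = build_gmcs_milp(chain, g)
        assert int(spec.integer.sum()) == len(spec.y_index) == 3
        dump = spec.to_lp_string()
        assert dump.startswith("Minimize") and "Binaries" in dump
        assert "y[g1]" in dump
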