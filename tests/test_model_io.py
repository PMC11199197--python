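"""Model I/O, media, flux-consistency pruning, and FBA."""

import itertools

import numpy as np
import pytest

from gemcuts import (
    InfeasibleModelError,
    ModelFormatError,
    apply_medium,
    fba,
    read_model,
    remove_blocked_reactions,
    write_model,
)
from gemcuts.gpr import evaluate_gpr, gpr_genes, gpr_to_string

from conftest import CAP, build_model, chain_model


def two_source_model():
    """Two carbon sources of capacity 3 and 4 feeding biomass."""
    return build_model([
        ("EX_A1", {"A1": -1.0}, -3.0, CAP, ""),
        ("EX_A2", {"A2": -1.0}, -4.0, CAP, ""),
        ("R1", {"A1": -1.0, "B": 1.0}, 0.0, CAP, "g1"),
        ("R2", {"A2": -1.0, "B": 1.0}, 0.0, CAP, "g2"),
        ("BIOMASS", {"B": -1.0}, 0.0, CAP, ""),
    ])


def _models_equal(m1, m2):
    assert m1.reactions == m2.reactions
    assert m1.metabolites == m2.metabolites
    assert np.allclose(m1.lb, m2.lb) and np.allclose(m1.ub, m2.ub)
    assert (m1.S != m2.S).nnz == 0
    assert m1.objective_id == m2.objective_id
    for rid in m1.reactions:
        e1, e2 = m1.gprs.get(rid), m2.gprs.get(rid)
        assert (e1 is None) == (e2 is None)
        if e1 is not None:
            genes = sorted(gpr_genes(e1) | gpr_genes(e2))
            for k in range(len(genes) + 1):
                for c in itertools.combinations(genes, k):
                    assert evaluate_gpr(e1, c) == evaluate_gpr(e2, c)


class TestRoundTrip:
    @pytest.mark.parametrize("ext", ["json", "xml", "mat"])
    def test_write_read_preserves_everything(self, tmp_path, ext):
        m = two_source_model()
        path = tmp_path / f"model.{ext}"
        write_model(m, path)
        _models_equal(m, read_model(path))

    def test_sbml_and_json_exports_agree(self, tmp_path, chain):
        write_model(chain, tmp_path / "m.xml")
        write_model(chain, tmp_path / "m.json")
        _models_equal(read_model(tmp_path / "m.xml"),
                      read_model(tmp_path / "m.json"))

    def test_complex_rule_survives_serialization(self, tmp_path):
        m = build_model([
            ("EX_A", {"A": -1.0}, -10.0, CAP, ""),
            ("R1", {"A": -1.0, "B": 1.0}, 0.0, CAP, "(g1 and g2) or g3"),
            ("BIOMASS", {"B": -1.0}, 0.0, CAP, ""),
        ])
        m2 = read_model(write_model(m, tmp_path / "m.json"))
        e1, e2 = m.gprs["R1"], m2.gprs["R1"]
        for k in range(4):
            for c in itertools.combinations(["g1", "g2", "g3"], k):
                assert evaluate_gpr(e1, c) == evaluate_gpr(e2, c)

    def test_empty_gpr_reads_back_as_no_rule(self, tmp_path, chain):
        m2 = read_model(write_model(chain, tmp_path / "m.json"))
        assert m2.gprs["BIOMASS"] is None
        assert m2.gprs["EX_M0"] is None

    def test_missing_file_and_unknown_format(self, tmp_path, chain):
        with pytest.raises(FileNotFoundError):
            read_model(tmp_path / "nope.json")
        with pytest.raises(ModelFormatError):
            write_model(chain, tmp_path / "m.xyz")
        with pytest.raises(ModelFormatError):
            read_model(write_model(chain, tmp_path / "m.json"),
                       format="weird")


class TestExchanges:
    def test_single_nonzero_column_convention(self, chain):
        assert chain.exchanges == ["EX_M0", "BIOMASS"]


class TestApplyMedium:
    def test_empty_map_closes_all_uptakes(self):
        m = apply_medium(two_source_model(), {})
        assert fba(m).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_current_medium_is_identity(self):
        m = two_source_model()
        m2 = apply_medium(m, {"EX_A1": 3.0, "EX_A2": 4.0})
        assert np.allclose(m.lb, m2.lb) and np.allclose(m.ub, m2.ub)

    def test_single_source_throughput_hand_lp(self):
        # keep only the capacity-3 source: optimum drops from 7 to 3
        m = apply_medium(two_source_model(), {"EX_A1": 3.0})
        assert fba(m).objective_value == pytest.approx(3.0)

    def test_non_exchange_key_rejected(self):
        with pytest.raises(ValueError, match="R1"):
            apply_medium(two_source_model(), {"R1": 5.0})

    def test_enlarging_medium_never_decreases_growth(self):
        m = two_source_model()
        media = [{}, {"EX_A1": 3.0}, {"EX_A1": 3.0, "EX_A2": 4.0}]
        vals = [fba(apply_medium(m, med)).objective_value for med in media]
        assert vals == sorted(vals)


class TestRemoveBlocked:
    def test_dead_end_reaction_removed(self):
        m = build_model([
            ("EX_A", {"A": -1.0}, -10.0, CAP, ""),
            ("R1", {"A": -1.0, "B": 1.0}, 0.0, CAP, "g1"),
            ("DEAD", {"X": -1.0, "Y": 1.0}, 0.0, CAP, "g9"),
            ("BIOMASS", {"B": -1.0}, 0.0, CAP, ""),
        ])
        out = remove_blocked_reactions(m)
        assert "DEAD" not in out.reactions
        assert "X" not in out.metabolites and "Y" not in out.metabolites

    def test_consistent_model_unchanged_and_idempotent(self, chain):
        out = remove_blocked_reactions(chain)
        assert out.reactions == chain.reactions
        out2 = remove_blocked_reactions(out)
        assert out2.reactions == out.reactions

    def test_blocked_cycle_removed_biomass_unchanged(self, chain):
        rows = [
            ("EX_M0", {"M0": -1.0}, -10.0, CAP, ""),
            ("R1", {"M0": -1.0, "M1": 1.0}, 0.0, CAP, "g1"),
            ("BIOMASS", {"M1": -1.0}, 0.0, CAP, ""),
            # 3-cycle disconnected from biomass, irreversible, no net input
            ("C1", {"X1": -1.0, "X2": 1.0}, 0.0, CAP, ""),
            ("C2", {"X2": -1.0, "X3": 1.0}, 0.0, CAP, ""),
            ("C3", {"X3": -1.0, "X1": 1.0, "X4": 1.0}, 0.0, CAP, ""),
        ]
        m = build_model(rows)
        before = fba(m).objective_value
        out = remove_blocked_reactions(m)
        assert set(out.reactions) == {"EX_M0", "R1", "BIOMASS"}
        assert fba(out).objective_value == pytest.approx(before)

    def test_infeasible_model_reported_not_emptied(self):
        # forced flux consuming a metabolite nothing produces
        m = build_model([
            ("R1", {"A": -1.0}, 1.0, 2.0, ""),
            ("BIOMASS", {"B": -1.0, "A": 0.0}, 0.0, CAP, ""),
            ("EX_B", {"B": 1.0}, 0.0, CAP, ""),
        ])
        with pytest.raises(InfeasibleModelError):
            remove_blocked_reactions(m)


class TestFBA:
    def test_linear_chain_throughput(self, chain):
        assert fba(chain).objective_value == pytest.approx(10.0)

    def test_bounded_middle_reaction_blocks_growth(self, chain):
        chain.ub[chain.reaction_index("R2")] = 0.0
        assert fba(chain).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_branched_capacities_sum_hand_lp(self):
        assert fba(two_source_model()).objective_value == pytest.approx(7.0)

    def test_min_sense_and_explicit_objective(self, chain):
        res = fba(chain, "R1", "min")
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_is_a_status_not_an_exception(self):
        m = build_model([
            ("R1", {"A": -1.0}, 1.0, 2.0, ""),
            ("BIOMASS", {"A": 1.0, "B": -1.0}, 0.0, 0.0, ""),
        ])
        m.lb[0] = 1.0
        res = fba(m)
        assert res.status == "infeasible" and res.objective_value is None
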