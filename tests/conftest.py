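"""Shared fixtures: toy models and the session-wide fixture bank."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import sparse

from gemcuts import MetabolicModel, fixture_bank, make_fixture, FixtureSpec
from gemcuts.gpr import evaluate_gpr, gpr_genes, parse_gpr

CAP = 1000.0


def build_model(rows, objective_id="BIOMASS"):
    """rows: (rxn_id, {met: coef}, lb, ub, rule). Test-side model builder,
    independent of gemcuts.fixtures internals."""
    mets, met_idx = [], {}
    data, ri, ci, rxn_ids, lbs, ubs, gprs = [], [], [], [], [], [], {}
    for j, (rid, stoich, lo, hi, rule) in enumerate(rows):
        rxn_ids.append(rid)
        lbs.append(lo)
        ubs.append(hi)
        gprs[rid] = parse_gpr(rule)
        for met, coef in stoich.items():
            if met not in met_idx:
                met_idx[met] = len(mets)
                mets.append(met)
            ri.append(met_idx[met])
            ci.append(j)
            data.append(float(coef))
    S = sparse.csc_matrix((data, (ri, ci)), shape=(len(mets), len(rxn_ids)))
    genes = sorted({g for e in gprs.values() if e is not None
                    for g in gpr_genes(e)})
    return MetabolicModel(metabolites=mets, reactions=rxn_ids, S=S,
                          lb=np.array(lbs), ub=np.array(ubs),
                          objective_id=objective_id, gprs=gprs, genes=genes)


def chain_model(n=3):
    rows = [("EX_M0", {"M0": -1.0}, -10.0, CAP, "")]
    rows += [(f"R{i}", {f"M{i-1}": -1.0, f"M{i}": 1.0}, 0.0, CAP, f"g{i}")
             for i in range(1, n + 1)]
    rows += [("BIOMASS", {f"M{n}": -1.0}, 0.0, CAP, "")]
    return build_model(rows)


def disabling_sets_oracle(expr, max_size=None):
    """Powerset oracle: all minimal falsifying gene sets of a rule.

    Enumerates every subset, keeps falsifying ones, then filters to the
    antichain of inclusion-minimal members — a different algorithm from
    the implementation's size-ascending pruned scan.
    """
    genes = sorted(gpr_genes(expr))
    falsifying = [frozenset(c)
                  for k in range(1, len(genes) + 1)
                  for c in itertools.combinations(genes, k)
                  if not evaluate_gpr(expr, c)]
    minimal = [s for s in falsifying
               if not any(t < s for t in falsifying)]
    if max_size is not None:
        minimal = [s for s in minimal if len(s) <= max_size]
    return sorted(minimal, key=lambda s: (len(s), tuple(sorted(s))))


@pytest.fixture(scope="session")
def bank():
    return fixture_bank(20, seed=1)


@pytest.fixture(scope="session")
def triple_fixture():
    """3-branch isoenzyme: planted {g1,g2,g3} whose 2-subsets are viable."""
    return make_fixture(FixtureSpec("isoenzyme_branch", n_reactions=3))


@pytest.fixture()
def chain():
    return chain_model(3)
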