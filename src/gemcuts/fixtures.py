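"""Synthetic metabolic models with planted, provable cut sets.

Every other module is tested against models built here, so nothing
external is ever downloaded.  Each fixture is a small growing network —
nutrient uptake feeding biomass through a structural motif — together
with its ground-truth minimal lethal gene sets, established by
exhaustive FBA screening at generation time and re-verifiable on demand.

Motifs
------
``linear_chain``      every gene is individually essential.
``isoenzyme_branch``  n parallel one-gene paths; the only cut set is all
                      n genes together (n = 3 plants a triple whose
                      2-subsets are non-lethal — the length-order case).
``enzyme_complex``    an AND rule: each subunit alone is a cut set.
``shared_gene``       ``(g1 and g2) or (g1 and g3)``: rows {g1} and
                      {g2,g3}, the strict-inclusion relation case.
``random_mix``        randomized layered networks with bounded-depth
                      AND/OR rules and gene reuse probability 0.2, so
                      shared-gene subset relations occur frequently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .config import DEFAULTS, GemcutsError
from .enumeration import brute_force_cut_sets, check_minimality, verify_cut_set
from .gpr import gpr_genes, parse_gpr
from .model_io import MetabolicModel, fba, write_model

logger = logging.getLogger("gemcuts.fixtures")

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "fixture_bank",
           "write_fixture_bank"]

MOTIFS = ("linear_chain", "isoenzyme_branch", "enzyme_complex",
          "shared_gene", "random_mix")

UPTAKE = 10.0
CAP = 1000.0


@dataclass(frozen=True)
class FixtureSpec:
    motif: str
    n_reactions: int = 3          # chain length / branch count, motif-specific
    n_genes: int = 10             # random_mix gene pool ceiling
    gpr_depth: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}; "
                             f"choose from {MOTIFS}")


@dataclass
class Fixture:
    spec: FixtureSpec
    model: MetabolicModel
    ground_truth: list[frozenset[str]]    # minimal lethal sets, |K| <= 3
    b: float                              # growth threshold used
    truth_max_length: int = 3

    def name(self) -> str:
        return f"{self.spec.motif}_s{self.spec.seed}_r{self.spec.n_reactions}"

    def recheck(self) -> None:
        """Re-verify ground truth lethality and minimality by fresh FBA."""
        for ks in self.ground_truth:
            if not verify_cut_set(self.model, ks, self.b):
                raise GemcutsError(f"planted set {sorted(ks)} is not lethal")
            if not check_minimality(self.model, ks, self.b):
                raise GemcutsError(f"planted set {sorted(ks)} is reducible")


def _model_from_table(rows: list[tuple], objective_id: str) -> MetabolicModel:
    """rows: (rxn_id, {met: coef}, lb, ub, rule_string)."""
    mets: list[str] = []
    met_idx: dict[str, int] = {}
    data, ri, ci = [], [], []
    rxn_ids, lbs, ubs = [], [], []
    gprs = {}
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


def _chain(n: int) -> list[tuple]:
    rows = [("EX_M0", {"M0": -1.0}, -UPTAKE, CAP, "")]
    for i in range(1, n + 1):
        rows.append((f"R{i}", {f"M{i-1}": -1.0, f"M{i}": 1.0},
                     0.0, CAP, f"g{i}"))
    rows.append(("BIOMASS", {f"M{n}": -1.0}, 0.0, CAP, ""))
    return rows


def _isoenzyme(n_branches: int) -> list[tuple]:
    rows = [("EX_A", {"A": -1.0}, -UPTAKE, CAP, "")]
    for i in range(1, n_branches + 1):
        rows.append((f"R{i}", {"A": -1.0, "B": 1.0}, 0.0, CAP, f"g{i}"))
    rows.append(("BIOMASS", {"B": -1.0}, 0.0, CAP, ""))
    return rows


def _complex() -> list[tuple]:
    return [("EX_A", {"A": -1.0}, -UPTAKE, CAP, ""),
            ("R1", {"A": -1.0, "B": 1.0}, 0.0, CAP, "g1 and g2"),
            ("BIOMASS", {"B": -1.0}, 0.0, CAP, "")]


def _shared() -> list[tuple]:
    return [("EX_A", {"A": -1.0}, -UPTAKE, CAP, ""),
            ("R1", {"A": -1.0, "B": 1.0}, 0.0, CAP,
             "(g1 and g2) or (g1 and g3)"),
            ("R2", {"B": -1.0, "C": 1.0}, 0.0, CAP, "g1"),
            ("BIOMASS", {"C": -1.0}, 0.0, CAP, "")]


def _random_gpr(rng: np.random.Generator, pool: list[str], used: list[str],
                depth: int, reuse_p: float = 0.2) -> str:
    """Bounded-depth AND/OR rule string with gene reuse probability 0.2."""
    def leaf() -> str:
        if used and (rng.random() < reuse_p or len(used) == len(pool)):
            return str(rng.choice(used))
        fresh = [g for g in pool if g not in used]
        g = str(rng.choice(fresh))
        used.append(g)
        return g

    def expr(d: int) -> str:
        if d == 0 or rng.random() < 0.35:
            return leaf()
        op = " and " if rng.random() < 0.5 else " or "
        k = int(rng.integers(2, 4))
        return "(" + op.join(expr(d - 1) for _ in range(k)) + ")"

    return expr(depth)


def _random_mix(spec: FixtureSpec) -> list[tuple]:
    rng = np.random.default_rng(spec.seed)
    n_mid = int(rng.integers(2, 5))
    pool = [f"g{i}" for i in range(1, spec.n_genes + 1)]
    used: list[str] = []
    rows = [("EX_A", {"A": -1.0}, -UPTAKE, CAP, "")]
    k = 0
    mids = [f"P{i}" for i in range(n_mid)]
    for met in mids:
        for _ in range(int(rng.integers(1, 3))):
            k += 1
            rows.append((f"R{k}", {"A": -1.0, met: 1.0}, 0.0, CAP,
                         _random_gpr(rng, pool, used, spec.gpr_depth)))
    # biomass needs every Z precursor; each produced from random midpoints
    n_prec = int(rng.integers(1, 3))
    biomass_stoich = {}
    for z in range(n_prec):
        met = f"Z{z}"
        biomass_stoich[met] = -1.0
        for src in rng.choice(mids, size=int(rng.integers(1, 3)),
                              replace=False):
            k += 1
            rows.append((f"R{k}", {str(src): -1.0, met: 1.0}, 0.0, CAP,
                         _random_gpr(rng, pool, used, spec.gpr_depth)))
    rows.append(("BIOMASS", biomass_stoich, 0.0, CAP, ""))
    return rows


def make_fixture(spec: FixtureSpec, truth_max_length: int = 3) -> Fixture:
    """Build a motif model and its brute-force ground truth.

    Deterministic per spec/seed.  The emitted model must grow (positive
    biomass optimum) and every ground-truth set is self-checked lethal
    and minimal at generation time; a motif instance that cannot grow
    raises a generation error.
    """
    if spec.motif == "linear_chain":
        rows = _chain(spec.n_reactions)
    elif spec.motif == "isoenzyme_branch":
        rows = _isoenzyme(spec.n_reactions)
    elif spec.motif == "enzyme_complex":
        rows = _complex()
    elif spec.motif == "shared_gene":
        rows = _shared()
    else:
        rows = _random_mix(spec)
    model = _model_from_table(rows, "BIOMASS")
    wt = fba(model)
    if wt.status != "optimal" or wt.objective_value <= DEFAULTS.flux_tol:
        raise GemcutsError(
            f"motif {spec.motif!r} (seed {spec.seed}) does not grow")
    b = DEFAULTS.growth_frac * wt.objective_value
    truth = brute_force_cut_sets(model, truth_max_length, b)
    fx = Fixture(spec=spec, model=model, ground_truth=truth, b=b,
                 truth_max_length=truth_max_length)
    fx.recheck()
    return fx


def fixture_bank(n_models: int = 20, seed: int = 1) -> list[Fixture]:
    """>= 20 growing models spanning all motifs, reproducible per seed.

    The first six are the deterministic motif instances (including the
    3-branch isoenzyme whose planted triple has non-lethal 2-subsets);
    the remainder are random mixes with seeds derived from ``seed``,
    skipping the occasional non-growing draw.
    """
    bank = [
        make_fixture(FixtureSpec("linear_chain", n_reactions=3)),
        make_fixture(FixtureSpec("linear_chain", n_reactions=5)),
        make_fixture(FixtureSpec("isoenzyme_branch", n_reactions=2)),
        make_fixture(FixtureSpec("isoenzyme_branch", n_reactions=3)),
        make_fixture(FixtureSpec("enzyme_complex")),
        make_fixture(FixtureSpec("shared_gene")),
    ]
    draw = 0
    while len(bank) < n_models:
        sub = seed * 1000 + draw
        draw += 1
        if draw > 50 * n_models:  # pragma: no cover - generator defect guard
            raise GemcutsError("could not generate enough growing models")
        try:
            n_genes = 6 + (sub % 9)  # 6..14 genes keeps the oracle fast
            bank.append(make_fixture(
                FixtureSpec("random_mix", n_genes=n_genes,
                            gpr_depth=2, seed=sub)))
        except GemcutsError:
            continue
    return bank


def write_fixture_bank(directory, bank: list[Fixture]) -> Path:
    """Emit every fixture in all three dialects plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for fx in bank:
        base = fx.name()
        for ext in ("xml", "json", "mat"):
            write_model(fx.model, directory / f"{base}.{ext}")
        manifest.append({
            "name": base,
            "motif": fx.spec.motif,
            "seed": fx.spec.seed,
            "files": [f"{base}.xml", f"{base}.json", f"{base}.mat"],
            "growth_threshold": fx.b,
            "truth_max_length": fx.truth_max_length,
            "ground_truth": [sorted(s) for s in fx.ground_truth],
        })
    out = directory / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2) + "\n")
    return out
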