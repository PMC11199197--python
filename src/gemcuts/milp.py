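"""Dual (Farkas-certificate) MILPs whose minimal supports are cut sets.

A knockout set K is lethal when the LP ``max c'v : S v = 0, lb <= v <= ub``
restricted by the knockout cannot reach the growth threshold b.  By LP
duality that infeasibility has a certificate: multipliers u (steady-state
rows), mu+/mu- (bound rows) and, for each knocked reaction j, a free
multiplier on the added constraint v_j = 0, such that

    S' u + mu+ - mu- + [knockout terms] = c        (one row per reaction)
    ub' mu+ - lb' mu- <= b - eps                   (dual objective cap)

The MILP searches over knockouts: a binary selector y_g per knockable
unit (gene, nutrient pseudo-gene, or reaction), a continuous activation
z_p in [0,1] per G-matrix row with z_p <= y_g for every g in the row (a
row's knockout terms switch on only when ALL its genes are selected),
and a certificate variable eta_{p,j} per nonzero G entry linked by
|eta| <= M z_p.  Nutrient rows close only the uptake direction
(v_j >= 0 added), so their eta is sign-constrained to <= 0.  Minimizing
sum(y) makes optimal supports minimal cut sets; fixing sum(y) = k gives
the length-k layer of the enumeration.

The binary assignment contract: y is feasible iff the biomass LP maximum
after removing every reaction disabled by the selected knockout is below
b.  One deliberate one-sided approximation: the certificate encodes a
knocked reaction as v_j = 0 *added to its original bounds*; for a
reaction with a forced positive lower bound this over-claims lethality.
Every incumbent is therefore re-verified by an independent FBA call
before being reported — verification, not the solver certificate, is the
authority.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .config import DEFAULTS, GemcutsError
from .gmatrix import GMatrix, NUTRIENT_PREFIX, is_nutrient_label
from .model_io import MetabolicModel, fba

logger = logging.getLogger("gemcuts.milp")

__all__ = ["MILPSpec", "MILPOptions", "LinearRow",
           "build_gmcs_milp", "build_mcs_milp", "apply_target_kos"]


@dataclass
class LinearRow:
    """One linear constraint: lb <= coefs . x <= ub."""

    idx: np.ndarray
    val: np.ndarray
    lb: float
    ub: float
    name: str = ""


@dataclass
class MILPOptions:
    """Knobs of the MILP construction.

    ``b`` is the minimum biomass flux declared "growth" (flux units);
    when None it defaults to ``growth_frac`` x the wild-type optimum —
    scale-free across model unit conventions.  ``big_m`` bounds the
    certificate variables; a too-small M silently loses solutions, so
    the value used is logged at build time.
    """

    b: float | None = None
    growth_frac: float = DEFAULTS.growth_frac
    big_m: float = DEFAULTS.big_m
    eps: float = DEFAULTS.eps
    knockable: list[str] | None = None   # reaction-level only
    exclude_exchanges: bool = True       # reaction-level default exclusions


@dataclass
class MILPSpec:
    """Backend-agnostic mixed-integer program.

    Variables carry names, bounds, and an integrality mask; constraints
    are two-sided linear rows.  ``y_index`` maps each knockable label
    (gene / pseudo-gene / reaction id) to its binary selector variable.
    """

    names: list[str]
    lb: np.ndarray
    ub: np.ndarray
    integer: np.ndarray           # bool mask
    obj: np.ndarray
    rows: list[LinearRow]
    y_index: dict[str, int]
    kind: str                     # 'gene' | 'reaction'
    b: float
    big_m: float
    eps: float
    gmatrix: GMatrix | None = None
    #: every label a user may legally name (all model genes + pseudo-genes,
    #: or all reactions), a superset of the knockable labels in y_index
    known_labels: frozenset = frozenset()

    @property
    def n_vars(self) -> int:
        return len(self.names)

    def constraint_matrix(self):
        """Materialize rows as (A csr, row_lb, row_ub)."""
        if not self.rows:
            A = sparse.csr_matrix((0, self.n_vars))
            return A, np.zeros(0), np.zeros(0)
        data, ri, ci = [], [], []
        for k, row in enumerate(self.rows):
            ri.extend([k] * len(row.idx))
            ci.extend(row.idx)
            data.extend(row.val)
        A = sparse.csr_matrix((data, (ri, ci)),
                              shape=(len(self.rows), self.n_vars))
        rlb = np.array([r.lb for r in self.rows])
        rub = np.array([r.ub for r in self.rows])
        return A, rlb, rub

    def cardinality_row(self, k: int) -> LinearRow:
        """sum(y) = k — one enumeration layer."""
        idx = np.fromiter(self.y_index.values(), dtype=int)
        return LinearRow(idx, np.ones(len(idx)), float(k), float(k),
                         name=f"layer[{k}]")

    def exclusion_row(self, members) -> LinearRow:
        """Support cut: sum_{g in members} y_g <= |members| - 1.

        Excludes the found solution and every superset of it.
        """
        idx = np.array(sorted(self.y_index[m] for m in members), dtype=int)
        return LinearRow(idx, np.ones(len(idx)), -np.inf, float(len(idx) - 1),
                         name="exclude[" + ",".join(sorted(members)) + "]")

    def nogood_row(self, members) -> LinearRow:
        """Ban exactly this assignment, leaving its supersets reachable.

        sum_{g in K} y_g - sum_{g not in K} y_g <= |K| - 1.  Used for
        incumbents that fail FBA verification: a support cut would also
        remove genuine larger cut sets containing the spurious one.
        """
        members = set(members)
        idx, val = [], []
        for lab, j in self.y_index.items():
            idx.append(j)
            val.append(1.0 if lab in members else -1.0)
        order = np.argsort(idx)
        return LinearRow(np.array(idx)[order], np.array(val)[order],
                         -np.inf, float(len(members) - 1),
                         name="nogood[" + ",".join(sorted(members)) + "]")

    def fix_labels_to_zero(self, labels) -> None:
        for lab in labels:
            self.ub[self.y_index[lab]] = 0.0

    def to_lp_string(self) -> str:
        """CPLEX-LP-format dump for debugging."""
        def term(v, j):
            return f"{'+' if v >= 0 else '-'} {abs(v):.12g} {self.names[j]} "

        out = ["Minimize", " obj: " + "".join(
            term(v, j) for j, v in enumerate(self.obj) if v)]
        out.append("Subject To")
        for k, r in enumerate(self.rows):
            expr = "".join(term(v, j) for j, v in zip(r.idx, r.val))
            nm = r.name or f"c{k}"
            if r.lb == r.ub:
                out.append(f" {nm}: {expr}= {r.lb:.12g}")
            else:
                if np.isfinite(r.ub):
                    out.append(f" {nm}: {expr}<= {r.ub:.12g}")
                if np.isfinite(r.lb):
                    out.append(f" {nm}_lo: {expr}>= {r.lb:.12g}")
        out.append("Bounds")
        for j, nm in enumerate(self.names):
            lo = "-inf" if not np.isfinite(self.lb[j]) else f"{self.lb[j]:.12g}"
            hi = "+inf" if not np.isfinite(self.ub[j]) else f"{self.ub[j]:.12g}"
            out.append(f" {lo} <= {nm} <= {hi}")
        ints = [self.names[j] for j in np.flatnonzero(self.integer)]
        if ints:
            out.append("Binaries")
            out.append(" " + " ".join(ints))
        out.append("End")
        return "\n".join(out) + "\n"


class _Builder:
    def __init__(self):
        self.names: list[str] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integer: list[bool] = []
        self.obj: list[float] = []
        self.rows: list[LinearRow] = []

    def var(self, name, lo, hi, integer=False, obj=0.0) -> int:
        self.names.append(name)
        self.lb.append(lo)
        self.ub.append(hi)
        self.integer.append(integer)
        self.obj.append(obj)
        return len(self.names) - 1

    def row(self, coefs: dict[int, float], lo, hi, name="") -> None:
        idx = np.fromiter(coefs.keys(), dtype=int)
        val = np.fromiter(coefs.values(), dtype=float)
        self.rows.append(LinearRow(idx, val, lo, hi, name))


def _growth_threshold(model: MetabolicModel, options: MILPOptions) -> float:
    wt = fba(model)
    if wt.status == "unbounded":
        raise GemcutsError("biomass flux is unbounded: target always feasible, "
                           "no finite growth threshold exists")
    if wt.status != "optimal":
        raise GemcutsError(f"wild-type FBA failed with status {wt.status!r}")
    if options.b is not None:
        return float(options.b)
    if wt.objective_value <= 0:
        raise GemcutsError("wild-type biomass optimum is 0; the model does "
                           "not grow, so cut sets are undefined")
    return options.growth_frac * wt.objective_value


def _build(model: MetabolicModel, g: GMatrix, kind: str,
           options: MILPOptions) -> MILPSpec:
    if g.n_rows == 0:
        raise GemcutsError("G matrix has no rows: nothing is knockable")
    b = _growth_threshold(model, options)
    M, eps = options.big_m, options.eps
    logger.info("building %s-level MILP: %d rows, b=%.6g, M=%g, eps=%g",
                kind, g.n_rows, b, M, eps)

    bld = _Builder()
    m_mets, n_rxn = model.S.shape
    u = [bld.var(f"u[{mid}]", -np.inf, np.inf) for mid in model.metabolites]
    mup = [bld.var(f"mup[{rid}]", 0.0,
                   0.0 if not np.isfinite(model.ub[j]) else np.inf)
           for j, rid in enumerate(model.reactions)]
    mun = [bld.var(f"mun[{rid}]", 0.0,
                   0.0 if not np.isfinite(model.lb[j]) else np.inf)
           for j, rid in enumerate(model.reactions)]

    labels = g.labels()
    y = {lab: bld.var(f"y[{lab}]", 0.0, 1.0, integer=True, obj=1.0)
         for lab in labels}
    z = [bld.var(f"z[{p}]", 0.0, 1.0) for p in range(g.n_rows)]

    mat = g.matrix.tocsr()
    # eta variables + big-M links; column -> its eta terms
    col_eta: dict[int, list[int]] = {}
    for p in range(g.n_rows):
        nutrient = any(is_nutrient_label(lab) for lab in g.row_sets[p])
        for j in mat.getrow(p).indices:
            hi = 0.0 if nutrient else M
            e = bld.var(f"eta[{p},{model.reactions[j]}]", -M, hi)
            col_eta.setdefault(int(j), []).append(e)
            # |eta| <= M z_p  (upper link redundant for nutrient rows)
            bld.row({e: 1.0, z[p]: M}, 0.0, np.inf, f"lnk_lo[{p},{j}]")
            if not nutrient:
                bld.row({e: 1.0, z[p]: -M}, -np.inf, 0.0, f"lnk_hi[{p},{j}]")
        for lab in g.row_sets[p]:
            bld.row({z[p]: 1.0, y[lab]: -1.0}, -np.inf, 0.0,
                    f"act[{p},{lab}]")

    # dual feasibility rows: S'u + mu+ - mu- + sum(eta) = c
    St = model.S.tocsc().T.tocsr()
    obj_j = model.objective_index
    for j in range(n_rxn):
        coefs: dict[int, float] = {}
        rj = St.getrow(j)
        for i, v in zip(rj.indices, rj.data):
            coefs[u[i]] = float(v)
        coefs[mup[j]] = coefs.get(mup[j], 0.0) + 1.0
        coefs[mun[j]] = coefs.get(mun[j], 0.0) - 1.0
        for e in col_eta.get(j, ()):
            coefs[e] = coefs.get(e, 0.0) + 1.0
        c_j = 1.0 if j == obj_j else 0.0
        bld.row(coefs, c_j, c_j, f"dual[{model.reactions[j]}]")

    # dual objective cap: ub'mu+ - lb'mu- <= b - eps
    cap: dict[int, float] = {}
    for j in range(n_rxn):
        if np.isfinite(model.ub[j]) and model.ub[j] != 0.0:
            cap[mup[j]] = float(model.ub[j])
        if np.isfinite(model.lb[j]) and model.lb[j] != 0.0:
            cap[mun[j]] = -float(model.lb[j])
    if not cap:
        cap = {mup[obj_j]: float(model.ub[obj_j])}
    bld.row(cap, -np.inf, b - eps, "dual_obj")

    return MILPSpec(
        names=bld.names,
        lb=np.array(bld.lb), ub=np.array(bld.ub),
        integer=np.array(bld.integer, dtype=bool),
        obj=np.array(bld.obj),
        rows=bld.rows,
        y_index=y, kind=kind, b=b, big_m=M, eps=eps, gmatrix=g,
        known_labels=frozenset(model.genes) | set(labels)
        if kind == "gene" else frozenset(model.reactions))


def build_gmcs_milp(model: MetabolicModel, g: GMatrix,
                    options: MILPOptions | None = None) -> MILPSpec:
    """Gene-level cut-set MILP over a built G matrix.

    A selector assignment y is feasible iff knocking out the selected
    genes (and closing selected nutrient uptakes) drops the biomass LP
    maximum below b; optimal solutions have minimum support.
    """
    return _build(model, g, "gene", options or MILPOptions())


def build_mcs_milp(model: MetabolicModel,
                   options: MILPOptions | None = None) -> MILPSpec:
    """Reaction-level cut-set MILP: identity G over knockable reactions.

    By default the biomass reaction and all exchanges are excluded from
    the knockable set (overridable via ``options.knockable``).
    """
    options = options or MILPOptions()
    if options.knockable is not None:
        knockable = list(options.knockable)
        unknown = [r for r in knockable if r not in model._rxn_index]
        if unknown:
            raise ValueError(f"unknown reactions in knockable set: {unknown}")
    else:
        excluded = {model.objective_id}
        if options.exclude_exchanges:
            excluded |= set(model.exchanges)
        knockable = [r for r in model.reactions if r not in excluded]
    if not knockable:
        raise ValueError("knockable reaction set is empty")
    rows = [frozenset({rid}) for rid in sorted(knockable)]
    n = len(model.reactions)
    data_i = list(range(len(rows)))
    data_j = [model.reaction_index(next(iter(s))) for s in rows]
    mat = sparse.csr_matrix((np.ones(len(rows), dtype=np.int8),
                             (data_i, data_j)), shape=(len(rows), n))
    g = GMatrix(row_sets=rows, matrix=mat,
                reaction_ids=list(model.reactions), relations=[])
    return _build(model, g, "reaction", options)


def apply_target_kos(spec: MILPSpec, g: GMatrix, target_genes) -> MILPSpec:
    """Restrict solutions to a subset of genes.

    Selectors of every label outside ``target_genes`` are fixed to 0, so
    any row whose gene set is not contained in the target can never
    activate.  Unknown gene ids raise, listing the offenders.
    """
    target = set(target_genes)
    unknown = sorted(t for t in target if t not in spec.known_labels)
    if unknown:
        raise ValueError(f"unknown gene ids in targetKOs: {unknown}")
    spec.fix_labels_to_zero(set(spec.y_index) - target)
    return spec
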