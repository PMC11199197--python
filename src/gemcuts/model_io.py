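"""Constraint-based model I/O and basic flux analysis.

Models are held in a light array-based container (:class:`MetabolicModel`)
carrying exactly what cut-set computation needs: the stoichiometric matrix
S, flux bounds, a single biomass objective, and parsed GPR rules.  File
formats (SBML Level 3 + fbc, COBRA-style JSON, COBRA Toolbox MAT) are read
and written through cobrapy so dialect quirks stay the format library's
problem; FBA and flux variability run directly on the arrays via HiGHS
(`scipy.optimize.linprog`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .config import DEFAULTS, GemcutsError
from .gpr import GPRExpression, GPRParseError, gpr_genes, gpr_to_string, parse_gpr

logger = logging.getLogger("gemcuts.model_io")

__all__ = [
    "MetabolicModel",
    "FBAResult",
    "ModelFormatError",
    "InfeasibleModelError",
    "read_model",
    "write_model",
    "apply_medium",
    "remove_blocked_reactions",
    "fba",
]


class ModelFormatError(GemcutsError):
    """Unknown or malformed model dialect."""


class InfeasibleModelError(GemcutsError):
    """The model admits no steady-state flux distribution at all."""


@dataclass
class MetabolicModel:
    """Stoichiometric model with bounds, biomass objective and GPR rules.

    Invariants: ``lb <= ub`` everywhere; every gene referenced by a rule
    is listed in ``genes``; ``objective_id`` is one of ``reactions`` (a
    single biomass reaction — multi-objective models are rejected at
    read time).  ``S`` is metabolites x reactions, sparse.
    """

    metabolites: list[str]
    reactions: list[str]
    S: sparse.spmatrix
    lb: np.ndarray
    ub: np.ndarray
    objective_id: str
    gprs: dict[str, GPRExpression | None]
    genes: list[str]
    _rxn_index: dict[str, int] = field(default=None, repr=False)  # type: ignore

    def __post_init__(self):
        self.S = sparse.csc_matrix(self.S)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self._rxn_index = {r: j for j, r in enumerate(self.reactions)}
        self.validate()

    # -- bookkeeping -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.reactions)
        if self.S.shape != (len(self.metabolites), n):
            raise ValueError("S shape does not match metabolite/reaction lists")
        if len(self._rxn_index) != n:
            raise ValueError("duplicate reaction identifiers")
        if np.any(self.lb > self.ub):
            bad = self.reactions[int(np.argmax(self.lb > self.ub))]
            raise ValueError(f"lb > ub for reaction {bad!r}")
        if self.objective_id not in self._rxn_index:
            raise ValueError(f"objective {self.objective_id!r} is not a reaction")
        declared = set(self.genes)
        for rid, expr in self.gprs.items():
            missing = gpr_genes(expr) - declared
            if missing:
                raise ValueError(
                    f"reaction {rid!r} references undeclared genes {sorted(missing)}")

    def reaction_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"unknown reaction {rid!r}") from None

    @property
    def objective_index(self) -> int:
        return self._rxn_index[self.objective_id]

    @property
    def exchanges(self) -> list[str]:
        """Reactions with exactly one nonzero stoichiometric entry."""
        nnz = np.diff(self.S.tocsc().indptr)
        return [r for r, k in zip(self.reactions, nnz) if k == 1]

    def reversible(self, rid: str) -> bool:
        return self.lb[self.reaction_index(rid)] < 0

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            objective_id=self.objective_id,
            gprs=dict(self.gprs),
            genes=list(self.genes),
        )

    def knockout_reactions(self, gene_ids) -> list[str]:
        """Reactions whose GPR evaluates false when these genes are knocked."""
        ko = set(gene_ids)
        from .gpr import evaluate_gpr
        return [rid for rid, expr in self.gprs.items()
                if expr is not None and not evaluate_gpr(expr, ko)]


# ---------------------------------------------------------------------------
# cobra conversion + file formats
# ---------------------------------------------------------------------------

def _from_cobra(cm) -> MetabolicModel:
    import cobra.util.array as cua

    mets = [m.id for m in cm.metabolites]
    rxns = [r.id for r in cm.reactions]
    S = sparse.csc_matrix(cua.create_stoichiometric_matrix(cm, array_type="lil"))
    lb = np.array([r.lower_bound for r in cm.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cm.reactions], dtype=float)

    objective = [r.id for r in cm.reactions if r.objective_coefficient]
    if len(objective) != 1:
        raise ModelFormatError(
            f"expected exactly one biomass objective reaction, found "
            f"{len(objective)}: {objective}")

    gprs: dict[str, GPRExpression | None] = {}
    for r in cm.reactions:
        try:
            gprs[r.id] = parse_gpr(r.gene_reaction_rule)
        except GPRParseError as e:
            raise GPRParseError(
                f"reaction {r.id!r}: {e}", e.position) from e
    genes = sorted({g.id for g in cm.genes}
                   | {g for e in gprs.values() for g in gpr_genes(e)})
    return MetabolicModel(metabolites=mets, reactions=rxns, S=S, lb=lb, ub=ub,
                          objective_id=objective[0], gprs=gprs, genes=genes)


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model("gemcuts")
    cmet = {}
    for mid in model.metabolites:
        m = cobra.Metabolite(mid)
        m.compartment = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
        cmet[mid] = m
    cm.add_metabolites(list(cmet.values()))
    S = model.S.tocsc()
    rxns = []
    for j, rid in enumerate(model.reactions):
        r = cobra.Reaction(rid)
        r.lower_bound = float(model.lb[j])
        r.upper_bound = float(model.ub[j])
        col = S[:, j]
        r.add_metabolites({cmet[model.metabolites[i]]: float(v)
                           for i, v in zip(col.indices, col.data)})
        rule = gpr_to_string(model.gprs.get(rid))
        if rule:
            r.gene_reaction_rule = rule
        rxns.append(r)
    cm.add_reactions(rxns)
    # declared genes without any rule occurrence survive as orphan genes
    import cobra.core as cc
    present = {g.id for g in cm.genes}
    for g in model.genes:
        if g not in present:
            cm.genes.append(cc.Gene(g))
    cm.objective = model.objective_id
    return cm


_EXTENSIONS = {".xml": "sbml", ".sbml": "sbml", ".json": "json", ".mat": "mat"}


def _resolve_format(path: Path, format: str) -> str:
    if format != "auto":
        if format not in ("sbml", "json", "mat"):
            raise ModelFormatError(f"unknown format {format!r}")
        return format
    fmt = _EXTENSIONS.get(path.suffix.lower())
    if fmt is None:
        raise ModelFormatError(
            f"cannot infer model format from suffix {path.suffix!r}")
    return fmt


def read_model(path, format: str = "auto") -> MetabolicModel:
    """Read SBML (fbc), COBRA-JSON, or COBRA Toolbox MAT into a model.

    GPR strings are parsed into expression trees at load time; the gene
    list is the union of declared gene objects and genes appearing in
    rules.  MAT files must follow the COBRA Toolbox struct layout
    (rxns, mets, S, lb, ub, grRules, genes, c); other layouts are
    rejected with a clear message.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    try:
        if fmt == "sbml":
            cm = cobra.io.read_sbml_model(str(path))
        elif fmt == "json":
            cm = cobra.io.load_json_model(str(path))
        else:
            cm = cobra.io.load_matlab_model(str(path))
    except GPRParseError:
        raise
    except Exception as e:
        raise ModelFormatError(f"could not read {path} as {fmt}: {e}") from e
    return _from_cobra(cm)


def write_model(model: MetabolicModel, path, format: str = "auto") -> Path:
    """Write a model; ``read_model(write_model(m))`` reproduces m."""
    import cobra.io

    path = Path(path)
    fmt = _resolve_format(path, format)
    cm = _to_cobra(model)
    if fmt == "sbml":
        cobra.io.write_sbml_model(cm, str(path))
    elif fmt == "json":
        cobra.io.save_json_model(cm, str(path))
    else:
        cobra.io.save_matlab_model(cm, str(path))
    return path


# ---------------------------------------------------------------------------
# media and pruning
# ---------------------------------------------------------------------------

def apply_medium(model: MetabolicModel, allowed_uptakes: dict) -> MetabolicModel:
    """Constrain nutrient availability through exchange bounds.

    Exchanges not named in the map get their uptake closed (lb -> 0);
    each listed exchange gets ``lb = -max_uptake``.  Secretion (upper)
    bounds are untouched.  Follows the convention that an exchange
    exports its metabolite at positive flux, so uptake is negative flux.
    """
    exchanges = set(model.exchanges)
    bad = [k for k in allowed_uptakes if k not in exchanges]
    if bad:
        raise ValueError(f"not exchange reactions: {sorted(bad)}")
    out = model.copy()
    for rid in exchanges:
        j = out.reaction_index(rid)
        if rid in allowed_uptakes:
            out.lb[j] = -float(allowed_uptakes[rid])
        else:
            out.lb[j] = max(out.lb[j], 0.0)
    return out


@dataclass
class FBAResult:
    status: str                 # 'optimal' | 'infeasible' | 'unbounded' | 'error'
    objective_value: float | None
    fluxes: np.ndarray | None
    solver_status: object = None


def fba(model: MetabolicModel, objective_id: str | None = None,
        sense: str = "max") -> FBAResult:
    """Flux balance analysis: optimize one flux over the steady-state cone.

    Solves ``opt c'v  s.t.  S v = 0, lb <= v <= ub`` with HiGHS.
    Infeasibility is an explicit status, never an exception.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    j = model.reaction_index(objective_id or model.objective_id)
    n = len(model.reactions)
    c = np.zeros(n)
    c[j] = -1.0 if sense == "max" else 1.0
    res = linprog(c, A_eq=model.S, b_eq=np.zeros(model.S.shape[0]),
                  bounds=np.column_stack([model.lb, model.ub]),
                  method="highs")
    if res.status == 0:
        val = res.x[j]
        return FBAResult("optimal", float(val), res.x, res.status)
    if res.status == 2:
        return FBAResult("infeasible", None, None, res.status)
    if res.status == 3:
        return FBAResult("unbounded", None, None, res.status)
    return FBAResult("error", None, None, res)


def remove_blocked_reactions(model: MetabolicModel,
                             tolerance: float | None = None) -> MetabolicModel:
    """Drop reactions that cannot carry flux, and orphaned metabolites.

    A reaction is blocked when its flux-variability range under the
    current bounds lies within ``[-tol, tol]`` (two LPs per reaction).
    The biomass optimum is unchanged within tolerance — blocked
    reactions carry no flux in any feasible distribution.  Idempotent.

    Raises
    ------
    InfeasibleModelError
        If the model has no steady-state flux distribution at all (the
        result would otherwise be a silently emptied model).
    """
    tol = DEFAULTS.flux_tol if tolerance is None else tolerance
    base = fba(model)
    if base.status == "infeasible":
        raise InfeasibleModelError(
            "model admits no steady-state flux; refusing to prune")
    n = len(model.reactions)
    blocked = np.zeros(n, dtype=bool)
    bounds = np.column_stack([model.lb, model.ub])
    zeros = np.zeros(model.S.shape[0])
    for j in range(n):
        c = np.zeros(n)
        c[j] = -1.0
        hi = linprog(c, A_eq=model.S, b_eq=zeros, bounds=bounds, method="highs")
        vmax = hi.x[j] if hi.status == 0 else np.inf
        c[j] = 1.0
        lo = linprog(c, A_eq=model.S, b_eq=zeros, bounds=bounds, method="highs")
        vmin = lo.x[j] if lo.status == 0 else -np.inf
        blocked[j] = (abs(vmax) <= tol) and (abs(vmin) <= tol)
    if not blocked.any():
        return model.copy()
    keep = ~blocked
    if not keep[model.objective_index]:
        raise InfeasibleModelError("biomass reaction itself is blocked")
    S = model.S.tocsc()[:, keep]
    kept_rxns = [r for r, k in zip(model.reactions, keep) if k]
    met_nnz = np.diff(sparse.csr_matrix(S).indptr)
    met_keep = met_nnz > 0
    S = sparse.csr_matrix(S)[met_keep, :]
    out = MetabolicModel(
        metabolites=[m for m, k in zip(model.metabolites, met_keep) if k],
        reactions=kept_rxns,
        S=S,
        lb=model.lb[keep],
        ub=model.ub[keep],
        objective_id=model.objective_id,
        gprs={r: model.gprs.get(r) for r in kept_rxns},
        genes=list(model.genes),
    )
    logger.info("removed %d blocked reactions, %d orphaned metabolites",
                int(blocked.sum()), int((~met_keep).sum()))
    after = fba(out)
    if base.status == "optimal" and after.status == "optimal":
        if abs(after.objective_value - base.objective_value) > 1e-6 * max(
                1.0, abs(base.objective_value)):
            raise GemcutsError("pruning changed the biomass optimum; "
                               "tolerance too loose for this model")
    return out
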