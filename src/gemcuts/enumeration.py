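"""Length-ordered enumeration of verified minimal cut sets.

The search is layered by cardinality: for k = 1..max_length the MILP is
constrained to ``sum(y) = k`` and solved repeatedly; each incumbent
support is mapped to a candidate intervention, re-verified by an
independent FBA call (the solver's certificate is never trusted on its
own), checked for irreducibility, excluded by a support cut
``sum_{g in support} y_g <= k - 1`` (which also bans every superset in
later layers), and the layer continues until infeasible.  Layering is
what guarantees completeness in increasing length order — enumerating
by free minimization with exclusion cuts can skip a longer solution
whose subsets interleave badly, the failure mode this module's layer
test exists to rule out.

`brute_force_cut_sets` is the independent oracle: exhaustive FBA
screening of all knockout combinations up to a length bound.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

from .config import DEFAULTS, BudgetExceededError
from .gmatrix import GMatrix, NUTRIENT_PREFIX, is_nutrient_label
from .milp import MILPSpec
from .model_io import MetabolicModel, fba
from .solvers import SolverParams, add_constraint, solve, translate

logger = logging.getLogger("gemcuts.enumeration")

__all__ = ["CutSetResult", "CutSetList", "enumerate_cut_sets",
           "verify_cut_set", "check_minimality", "brute_force_cut_sets",
           "results_to_tsv", "results_to_json"]


@dataclass(frozen=True)
class CutSetResult:
    """One enumerated intervention, FBA-verified and irreducible."""

    kind: str                     # 'gene' | 'reaction' | 'nutrient' | 'mixed'
    members: frozenset[str]
    order: int
    verified: bool
    minimal: bool
    status: str = "optimal"       # solver status of the producing solve
    objective: float | None = None

    def sort_key(self):
        return (self.order, tuple(sorted(self.members)))


class CutSetList(list):
    """Result list with an explicit completeness flag.

    ``complete`` is False when a solver time limit (or solution cap)
    interrupted the search, i.e. the list may be a prefix of the truth.
    """

    complete: bool = True


def _classify(members: frozenset[str], milp_kind: str) -> str:
    if milp_kind == "reaction":
        return "reaction"
    nutrients = sum(1 for m in members if is_nutrient_label(m))
    if nutrients == len(members):
        return "nutrient"
    return "mixed" if nutrients else "gene"


def _apply_knockout(model: MetabolicModel, members, kind_hint: str | None):
    """Return a bounds-modified copy implementing the intervention."""
    ko = model.copy()
    genes = set()
    for m in members:
        if is_nutrient_label(m):
            rid = m[len(NUTRIENT_PREFIX):]
            j = ko.reaction_index(rid)
            ko.lb[j] = max(ko.lb[j], 0.0)   # close uptake, keep secretion
        elif kind_hint != "reaction" and m in set(model.genes):
            genes.add(m)
        else:
            j = ko.reaction_index(m)
            ko.lb[j] = ko.ub[j] = 0.0
    if genes:
        for rid in model.knockout_reactions(genes):
            j = ko.reaction_index(rid)
            ko.lb[j] = ko.ub[j] = 0.0
    return ko


def verify_cut_set(model: MetabolicModel, members, b: float,
                   kind: str | None = None) -> bool:
    """Independent FBA check: is the intervention lethal?

    Gene members disable every reaction whose GPR they falsify; nutrient
    pseudo-genes close their uptake; reaction members zero their bounds.
    True iff the post-knockout biomass maximum is below ``b`` (an
    infeasible post-knockout model also counts as lethal).
    """
    res = fba(_apply_knockout(model, members, kind))
    if res.status == "infeasible":
        return True
    return res.status == "optimal" and res.objective_value < b


def check_minimality(model: MetabolicModel, members, b: float,
                     kind: str | None = None) -> bool:
    """Irreducibility: every (|K|-1)-subset must be non-lethal.

    Smaller subsets are covered by induction over the layered search
    (their minimal lethal subsets would have been found earlier).
    """
    members = frozenset(members)
    if len(members) <= 1:
        return True
    return not any(
        verify_cut_set(model, members - {m}, b, kind) for m in members)


def enumerate_cut_sets(milp: MILPSpec, model: MetabolicModel,
                       g: GMatrix | None = None,
                       max_length: int = 3,
                       max_solutions: int | float = float("inf"),
                       solver: str = "highs",
                       seed: int = 0,
                       time_limit: float | None = None,
                       params: SolverParams | None = None) -> CutSetList:
    """All verified minimal cut sets up to ``max_length``, shortest first.

    Deterministic given seed, backend, and inputs: incumbents from the
    solver pass through verification and are finally sorted by
    (order, lexicographic members), quarantining any solver
    nondeterminism.  On a per-solve time limit the partial results are
    returned with ``complete = False``; an incumbent that fails FBA
    verification is logged, excluded from the search, and never
    returned.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    params = params or SolverParams(
        time_limit=DEFAULTS.time_limit if time_limit is None else time_limit,
        seed=seed)
    out = CutSetList()
    found_sets: list[frozenset[str]] = []
    base = translate(milp, solver)

    for k in range(1, max_length + 1):
        layer = translate(milp, solver)
        layer.extra_rows = list(base.extra_rows)
        add_constraint(layer, milp.cardinality_row(k))
        logger.info("layer k=%d (%s)", k, solver)
        while True:
            res = solve(layer, params)
            if res.status == "infeasible":
                break
            if res.status == "time_limit":
                logger.warning("time limit at layer %d; results incomplete", k)
                out.complete = False
                out.sort(key=CutSetResult.sort_key)
                return out
            if res.status != "optimal":
                raise RuntimeError(
                    f"solver {solver} failed: {res.status} ({res.detail})")
            support = frozenset(
                lab for lab, j in milp.y_index.items() if res.x[j] > 0.5)
            if len(support) != k:  # numerically degenerate incumbent
                logger.warning("support size %d at layer %d; excluding",
                               len(support), k)
            verified = verify_cut_set(model, support, milp.b, milp.kind)
            if not verified:
                # spurious certificate (e.g. forced-flux reaction): ban only
                # this exact assignment so genuine supersets stay reachable
                logger.warning("incumbent %s failed FBA verification; "
                               "excluded", sorted(support))
                cut = milp.nogood_row(support)
                add_constraint(base, cut)
                add_constraint(layer, cut)
                continue
            cut = milp.exclusion_row(support)
            add_constraint(base, cut)
            add_constraint(layer, cut)
            if any(s < support for s in found_sets):
                continue  # superset of an earlier solution
            minimal = check_minimality(model, support, milp.b, milp.kind)
            if not minimal:
                logger.warning("incumbent %s verified but reducible; "
                               "excluded", sorted(support))
                continue
            found_sets.append(support)
            out.append(CutSetResult(
                kind=_classify(support, milp.kind), members=support,
                order=len(support), verified=True, minimal=True,
                status=res.status, objective=res.objective))
            logger.info("cut set found: %s", sorted(support))
            if len(out) >= max_solutions:
                out.complete = False
                out.sort(key=CutSetResult.sort_key)
                return out
    out.sort(key=CutSetResult.sort_key)
    return out


def brute_force_cut_sets(model: MetabolicModel, max_length: int, b: float,
                         candidates=None, kind: str | None = None,
                         budget: int | None = None) -> list[frozenset[str]]:
    """Exhaustive FBA screening: the enumeration oracle.

    Tests every candidate combination up to ``max_length`` in size order,
    skipping supersets of already-found lethal sets, so the output is
    exactly the minimal lethal sets.  ``candidates`` defaults to the
    model's genes; pass reaction ids with ``kind='reaction'`` for
    reaction-level screening, and include ``uptake:<exchange>``
    pseudo-genes for nutrient interventions.  Exceeding ``budget`` FBA
    calls raises — never a silent truncation.
    """
    pool = sorted(candidates if candidates is not None else model.genes)
    budget = DEFAULTS.work_budget if budget is None else budget
    found: list[frozenset[str]] = []
    work = 0
    for k in range(1, max_length + 1):
        for combo in itertools.combinations(pool, k):
            cand = frozenset(combo)
            if any(f <= cand for f in found):
                continue
            work += 1
            if work > budget:
                raise BudgetExceededError(
                    f"brute force budget exceeded after {work - 1} FBA calls")
            if verify_cut_set(model, cand, b, kind):
                found.append(cand)
    return sorted(found, key=lambda s: (len(s), tuple(sorted(s))))


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def results_to_tsv(results) -> str:
    """Stable TSV (order, members, kind, verified) for regression diffs."""
    lines = ["order\tmembers\tkind\tverified"]
    for r in sorted(results, key=CutSetResult.sort_key):
        lines.append(f"{r.order}\t{','.join(sorted(r.members))}\t"
                     f"{r.kind}\t{str(r.verified).lower()}")
    return "\n".join(lines) + "\n"


def results_to_json(results, complete: bool = True) -> str:
    payload = {
        "complete": complete,
        "cut_sets": [
            {"order": r.order, "members": sorted(r.members), "kind": r.kind,
             "verified": r.verified, "minimal": r.minimal,
             "solver_status": r.status}
            for r in sorted(results, key=CutSetResult.sort_key)],
    }
    return json.dumps(payload, indent=2) + "\n"
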