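"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule states which gene combinations keep a reaction catalysed:
``"g1 and (g2 or g3)"`` needs g1 together with at least one of g2/g3.
This module parses rule strings into AND/OR trees, evaluates them under
gene knockouts, converts them into artificial reaction networks (so rule
satisfiability becomes an LP feasibility question), and enumerates the
minimal gene sets that falsify a rule — the raw material of the G matrix.

Grammar (operators case-insensitive, AND binds tighter than OR)::

    expr   := term ("or" term)*
    term   := factor ("and" factor)*
    factor := gene | "(" expr ")"

Parsing and evaluation are iterative (explicit stacks): published
genome-scale models contain rules with thousands of literals and deeply
nested parentheses, which must not hit the interpreter recursion limit.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Iterator

from .config import DEFAULTS, BudgetExceededError

__all__ = [
    "GPRExpression",
    "GPRParseError",
    "parse_gpr",
    "gpr_to_string",
    "evaluate_gpr",
    "gpr_genes",
    "gpr_operator_count",
    "gpr_stats",
    "ArtificialGPRNetwork",
    "gpr_to_network",
    "minimal_disabling_sets",
]

GENE, AND, OR = "GENE", "AND", "OR"


@dataclass(frozen=True)
class GPRExpression:
    """Node of a boolean AND/OR tree over gene identifiers.

    Internal nodes (`kind` AND/OR) have >= 2 children and same-operator
    children are flattened into them; a leaf carries a non-empty gene id.
    Duplicate gene occurrences are preserved in the tree (they matter for
    reproducing published rule statistics); logic-level operations treat
    genes as atomic, so a knockout silences every occurrence at once.
    """

    kind: str
    gene: str | None = None
    children: tuple["GPRExpression", ...] = ()

    def __post_init__(self):
        if self.kind == GENE:
            if not self.gene:
                raise ValueError("gene leaf requires a non-empty id")
        elif self.kind in (AND, OR):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind} node requires >= 2 children")
        else:
            raise ValueError(f"unknown node kind {self.kind!r}")

    def __repr__(self):  # pragma: no cover - debug aid
        return f"GPR<{gpr_to_string(self)}>"


def _gene(name: str) -> GPRExpression:
    return GPRExpression(GENE, gene=name)


def _node(kind: str, children: Iterable[GPRExpression]) -> GPRExpression:
    """Build an AND/OR node, flattening nested same-operator children."""
    flat: list[GPRExpression] = []
    for ch in children:
        if ch.kind == kind:
            flat.extend(ch.children)
        else:
            flat.append(ch)
    if len(flat) == 1:
        return flat[0]
    return GPRExpression(kind, children=tuple(flat))


class GPRParseError(ValueError):
    """Rule string violates the GPR grammar; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(rule: str) -> Iterator[tuple[str, str, int]]:
    """Yield (type, text, position); type in {'(', ')', 'op', 'gene'}."""
    pos = 0
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if m is None:
            break
        text = m.group(1)
        start = m.start(1)
        if text in "()":
            yield text, text, start
        elif text.lower() in ("and", "or"):
            yield "op", text.lower(), start
        else:
            yield "gene", text, start
        pos = m.end()


def parse_gpr(rule: str | None) -> GPRExpression | None:
    """Parse a GPR rule string into an expression tree.

    Returns ``None`` ("no rule") for an empty/whitespace rule: such a
    reaction can never be disabled through gene knockouts.  Operator
    precedence: AND binds tighter than OR.  The parser is a shunting-yard
    variant with explicit stacks, safe for rules with thousands of
    literals.

    Raises
    ------
    GPRParseError
        On unbalanced parentheses, dangling operators, empty operands,
        or two genes without a connective; the error names the offending
        character position.
    """
    if rule is None or not rule.strip():
        return None

    prec = {"or": 1, "and": 2}
    out: list[GPRExpression] = []       # operand stack
    ops: list[tuple[str, int]] = []     # ('and'|'or'|'(', position)

    def reduce_op(op: str, position: int) -> None:
        if len(out) < 2:
            raise GPRParseError(f"operator '{op}' is missing an operand", position)
        rhs, lhs = out.pop(), out.pop()
        out.append(_node(AND if op == "and" else OR, (lhs, rhs)))

    prev = "start"  # 'start' | 'gene' | 'op' | '(' | ')'
    last_pos = 0
    for ttype, text, tpos in _tokenize(rule):
        last_pos = tpos
        if ttype == "gene":
            if prev in ("gene", ")"):
                raise GPRParseError(
                    f"expected 'and'/'or' before {text!r}", tpos)
            out.append(_gene(text))
            prev = "gene"
        elif ttype == "op":
            if prev not in ("gene", ")"):
                raise GPRParseError(f"dangling operator '{text}'", tpos)
            while ops and ops[-1][0] != "(" and prec[ops[-1][0]] >= prec[text]:
                reduce_op(*ops.pop())
            ops.append((text, tpos))
            prev = "op"
        elif ttype == "(":
            if prev in ("gene", ")"):
                raise GPRParseError("expected 'and'/'or' before '('", tpos)
            ops.append(("(", tpos))
            prev = "("
        else:  # ')'
            if prev in ("op", "(", "start"):
                raise GPRParseError("empty operand before ')'", tpos)
            while ops and ops[-1][0] != "(":
                reduce_op(*ops.pop())
            if not ops:
                raise GPRParseError("unbalanced ')'", tpos)
            ops.pop()
            prev = ")"
    if prev in ("op", "start"):
        raise GPRParseError("rule ends with a dangling operator", last_pos)
    while ops:
        op, opos = ops.pop()
        if op == "(":
            raise GPRParseError("unbalanced '('", opos)
        reduce_op(op, opos)
    if len(out) != 1:
        raise GPRParseError("malformed rule", last_pos)
    return out[0]


def gpr_to_string(expr: GPRExpression | None) -> str:
    """Serialize a tree back to rule syntax; re-parses to an equal tree."""
    if expr is None:
        return ""
    # iterative post-order string build
    strings: dict[int, str] = {}
    stack: list[tuple[GPRExpression, bool]] = [(expr, False)]
    while stack:
        node, done = stack.pop()
        if node.kind == GENE:
            strings[id(node)] = node.gene  # type: ignore[assignment]
            continue
        if not done:
            stack.append((node, True))
            stack.extend((ch, False) for ch in node.children)
            continue
        sep = " and " if node.kind == AND else " or "
        parts = []
        for ch in node.children:
            s = strings[id(ch)]
            # OR child under AND needs parentheses; AND under OR does not,
            # but parenthesize any internal child for readability-free safety
            if ch.kind != GENE and (node.kind == AND or ch.kind == AND):
                s = f"({s})"
            parts.append(s)
        strings[id(node)] = sep.join(parts)
    return strings[id(expr)]


def evaluate_gpr(expr: GPRExpression | None, knocked: Iterable[str]) -> bool:
    """True iff the rule stays satisfied with the given genes knocked out.

    A missing rule ("no rule", spontaneous reaction) is always True.
    """
    if expr is None:
        return True
    ko = set(knocked)
    # iterative post-order evaluation
    values: dict[int, bool] = {}
    stack: list[tuple[GPRExpression, bool]] = [(expr, False)]
    while stack:
        node, done = stack.pop()
        if node.kind == GENE:
            values[id(node)] = node.gene not in ko
            continue
        if not done:
            stack.append((node, True))
            stack.extend((ch, False) for ch in node.children)
            continue
        vals = (values[id(ch)] for ch in node.children)
        values[id(node)] = all(vals) if node.kind == AND else any(vals)
    return values[id(expr)]


def gpr_genes(expr: GPRExpression | None) -> frozenset[str]:
    """Distinct gene identifiers referenced by a rule."""
    if expr is None:
        return frozenset()
    genes: set[str] = set()
    stack = [expr]
    while stack:
        node = stack.pop()
        if node.kind == GENE:
            genes.add(node.gene)  # type: ignore[arg-type]
        else:
            stack.extend(node.children)
    return frozenset(genes)


def gpr_operator_count(expr: GPRExpression | None) -> int:
    """Binary and/or connectives of the flattened tree.

    An n-child node contributes n-1; duplicate gene occurrences count,
    matching the fully left-associated reading of the rule string.
    """
    if expr is None:
        return 0
    count = 0
    stack = [expr]
    while stack:
        node = stack.pop()
        if node.kind != GENE:
            count += len(node.children) - 1
            stack.extend(node.children)
    return count


def gpr_stats(model) -> dict:
    """Per-reaction GPR complexity plus model-level maxima.

    Returns ``{"per_reaction": [(rxn_id, n_genes, n_operators), ...],
    "max_genes": int, "max_operators": int, "n_genes": int}`` with rows in
    model reaction order.  Reactions without a rule report (0, 0).
    """
    rows = []
    for rid in model.reactions:
        expr = model.gprs.get(rid)
        rows.append((rid, len(gpr_genes(expr)), gpr_operator_count(expr)))
    return {
        "per_reaction": rows,
        "max_genes": max((r[1] for r in rows), default=0),
        "max_operators": max((r[2] for r in rows), default=0),
        "n_genes": len(model.genes),
    }


def gpr_stats_tsv(model) -> str:
    stats = gpr_stats(model)
    lines = ["reaction\tn_genes\tn_operators"]
    lines += [f"{rid}\t{ng}\t{no}" for rid, ng, no in stats["per_reaction"]]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Artificial reaction networks: rule satisfiability as LP feasibility
# ---------------------------------------------------------------------------

@dataclass
class ArtificialGPRNetwork:
    """A GPR rule recast as a small metabolic network.

    Each expression node gets a pseudo-metabolite.  One input reaction per
    distinct gene produces that gene's metabolite (shared across all of the
    gene's occurrences); an AND node's reaction consumes one unit of every
    child metabolite, an OR node gets one converting reaction per child; a
    sink drains the root.  The sink can carry flux iff the boolean rule is
    satisfied by exactly the genes whose input reactions are open — so
    minimal cut sets of the sink over gene inputs are the rule's minimal
    disabling gene sets.
    """

    model: object                 # MetabolicModel over pseudo-species
    gene_inputs: dict[str, str]   # gene id -> input reaction id
    sink_id: str
    reaction_id: str


def gpr_to_network(expr: GPRExpression, reaction_id: str = "rxn",
                   cap: float = 1000.0) -> ArtificialGPRNetwork:
    """Transform a parsed rule into its artificial reaction network."""
    from .model_io import MetabolicModel  # local import avoids a cycle

    mets: list[str] = []
    rxn_ids: list[str] = []
    entries: list[tuple[int, int, float]] = []  # (met_idx, rxn_idx, coef)
    gene_met: dict[str, int] = {}
    gene_inputs: dict[str, str] = {}
    gprs: dict[str, GPRExpression | None] = {}

    def new_met(name: str) -> int:
        mets.append(name)
        return len(mets) - 1

    def new_rxn(name: str) -> int:
        rxn_ids.append(name)
        return len(rxn_ids) - 1

    counter = itertools.count()
    node_met: dict[int, int] = {}

    # post-order walk assigning metabolites and wiring reactions
    stack: list[tuple[GPRExpression, bool]] = [(expr, False)]
    while stack:
        node, done = stack.pop()
        if node.kind == GENE:
            g = node.gene
            if g not in gene_met:
                mi = new_met(f"gene[{g}]")
                gene_met[g] = mi
                ri = new_rxn(f"in[{g}]")
                entries.append((mi, ri, 1.0))
                gene_inputs[g] = rxn_ids[ri]
                gprs[rxn_ids[ri]] = _gene(g)
            node_met[id(node)] = gene_met[g]
            continue
        if not done:
            stack.append((node, True))
            stack.extend((ch, False) for ch in node.children)
            continue
        k = next(counter)
        mi = new_met(f"node{k}[{node.kind.lower()}]")
        node_met[id(node)] = mi
        if node.kind == AND:
            ri = new_rxn(f"and{k}")
            for ch in node.children:
                entries.append((node_met[id(ch)], ri, -1.0))
            entries.append((mi, ri, 1.0))
        else:  # OR: one converting reaction per child
            for j, ch in enumerate(node.children):
                ri = new_rxn(f"or{k}.{j}")
                entries.append((node_met[id(ch)], ri, -1.0))
                entries.append((mi, ri, 1.0))

    sink = new_rxn("sink")
    entries.append((node_met[id(expr)], sink, -1.0))
    sink_id = rxn_ids[sink]

    import numpy as np
    from scipy import sparse

    rows = [e[0] for e in entries]
    cols = [e[1] for e in entries]
    vals = [e[2] for e in entries]
    S = sparse.csc_matrix((vals, (rows, cols)), shape=(len(mets), len(rxn_ids)))
    n = len(rxn_ids)
    model = MetabolicModel(
        metabolites=mets,
        reactions=list(rxn_ids),
        S=S,
        lb=np.zeros(n),
        ub=np.full(n, cap),
        objective_id=sink_id,
        gprs={rid: gprs.get(rid) for rid in rxn_ids},
        genes=sorted(gene_inputs),
    )
    return ArtificialGPRNetwork(model=model, gene_inputs=gene_inputs,
                                sink_id=sink_id, reaction_id=reaction_id)


def network_sink_feasible(net: ArtificialGPRNetwork,
                          knocked: Iterable[str]) -> bool:
    """LP check: can the sink carry flux with these gene inputs closed?"""
    from .model_io import fba

    model = net.model.copy()
    for g in knocked:
        rid = net.gene_inputs.get(g)
        if rid is not None:
            j = model.reaction_index(rid)
            model.lb[j] = model.ub[j] = 0.0
    res = fba(model, net.sink_id, "max")
    return res.status == "optimal" and res.objective_value > DEFAULTS.flux_tol


# ---------------------------------------------------------------------------
# Minimal disabling gene sets
# ---------------------------------------------------------------------------

def _brute_force_disabling(expr: GPRExpression, genes: tuple[str, ...],
                           max_size: int, budget: int,
                           reaction_id: str) -> list[frozenset[str]]:
    found: list[frozenset[str]] = []
    work = 0
    for k in range(1, min(max_size, len(genes)) + 1):
        for combo in itertools.combinations(genes, k):
            work += 1
            if work > budget:
                raise BudgetExceededError(
                    f"minimal_disabling_sets budget exceeded for reaction "
                    f"{reaction_id!r} ({len(genes)} genes)")
            cand = frozenset(combo)
            if any(f <= cand for f in found):
                continue  # superset of a smaller minimal set
            if not evaluate_gpr(expr, cand):
                found.append(cand)
    return found


def minimal_disabling_sets(expr: GPRExpression | None,
                           max_size: int | None = None,
                           *,
                           reaction_id: str = "rxn",
                           bf_gene_limit: int | None = None,
                           budget: int | None = None) -> list[frozenset[str]]:
    """All minimal gene sets of size <= max_size that falsify the rule.

    Every returned set falsifies the rule, no proper subset of a returned
    set does, and the list is complete up to ``max_size`` (unbounded when
    None).  Order is deterministic: by size, then lexicographically.

    Rules with at most ``bf_gene_limit`` distinct genes are solved by exact
    subset brute force; larger rules are routed through the artificial
    reaction network, where disabling sets become reaction-level minimal
    cut sets of the sink and are enumerated by the package's MILP machinery.
    Work beyond ``budget`` raises :class:`BudgetExceededError` naming the
    reaction — never a silent truncation.
    """
    if expr is None:
        return []
    genes = tuple(sorted(gpr_genes(expr)))
    if not evaluate_gpr(expr, ()):  # never satisfiable: nothing to disable
        return []
    if max_size is None:
        max_size = len(genes)
    limit = DEFAULTS.bf_gene_limit if bf_gene_limit is None else bf_gene_limit
    budget = DEFAULTS.work_budget if budget is None else budget

    if len(genes) <= limit:
        found = _brute_force_disabling(expr, genes, max_size, budget,
                                       reaction_id)
    else:
        found = _milp_disabling(expr, max_size, reaction_id, budget)
    # a knockout of everything must falsify a satisfiable rule, so found
    # is nonempty whenever max_size >= the smallest disabling set
    return sorted(found, key=lambda s: (len(s), tuple(sorted(s))))


def _milp_disabling(expr: GPRExpression, max_size: int, reaction_id: str,
                    budget: int) -> list[frozenset[str]]:
    """Large-rule route: cut sets of the artificial network's sink."""
    from .milp import MILPOptions, build_mcs_milp
    from .enumeration import enumerate_cut_sets

    net = gpr_to_network(expr, reaction_id)
    opts = MILPOptions(knockable=sorted(net.gene_inputs.values()))
    spec = build_mcs_milp(net.model, opts)
    out = enumerate_cut_sets(spec, net.model, spec.gmatrix,
                             max_length=max_size,
                             max_solutions=budget)
    rxn_to_gene = {r: g for g, r in net.gene_inputs.items()}
    sets = [frozenset(rxn_to_gene[r] for r in res.members) for res in out]
    if not out.complete:
        raise BudgetExceededError(
            f"minimal_disabling_sets budget exceeded for reaction "
            f"{reaction_id!r}")
    return sets
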