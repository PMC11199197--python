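"""The G matrix: minimal gene-knockout sets vs the reactions they disable.

Row i is a distinct gene set that is a minimal disabling set for at least
one reaction; entry (i, j) = 1 iff knocking out all genes of row i
falsifies reaction j's GPR (a row may disable reactions for which it is
not minimal — the MILP needs each row's full knockout footprint).
``relations`` records every strict-inclusion pair between rows; nutrient
deprivations enter as pseudo-gene singleton rows closing one uptake.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .gpr import evaluate_gpr, gpr_to_string, minimal_disabling_sets

logger = logging.getLogger("gemcuts.gmatrix")

__all__ = ["GMatrix", "build_g_matrix", "extend_with_nutrients",
           "NUTRIENT_PREFIX"]

#: pseudo-gene label prefix for nutrient-deprivation rows
NUTRIENT_PREFIX = "uptake:"


def is_nutrient_label(label: str) -> bool:
    return label.startswith(NUTRIENT_PREFIX)


def _row_key(s: frozenset[str]):
    return (len(s), tuple(sorted(s)))


@dataclass
class GMatrix:
    """Sparse binary knockout matrix plus row subset relations.

    ``row_sets`` is ordered by (size, lexicographic member tuple);
    ``matrix`` is rows x reactions (CSR, bool); ``relations`` lists every
    ordered pair (p, q) with ``row_sets[q]`` a strict subset of
    ``row_sets[p]`` — the complete strict-inclusion order on rows.
    """

    row_sets: list[frozenset[str]]
    matrix: sparse.spmatrix
    reaction_ids: list[str]
    relations: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.row_sets)

    def labels(self) -> list[str]:
        """Union of all row members, sorted (genes + pseudo-genes)."""
        return sorted({g for s in self.row_sets for g in s})

    def row_columns(self, i: int) -> list[str]:
        row = self.matrix.getrow(i)
        return [self.reaction_ids[j] for j in row.indices]

    def to_coordinate_text(self) -> str:
        """Coordinate-format dump: 'gene1,gene2<TAB>reaction' per entry."""
        lines = []
        m = self.matrix.tocsr()
        for i, s in enumerate(self.row_sets):
            label = ",".join(sorted(s))
            for j in m.getrow(i).indices:
                lines.append(f"{label}\t{self.reaction_ids[j]}")
        return "\n".join(lines) + ("\n" if lines else "")


def _compute_relations(rows: list[frozenset[str]]) -> list[tuple[int, int]]:
    """All ordered pairs (p, q) with rows[q] ⊊ rows[p]."""
    rel = []
    for p, sp in enumerate(rows):
        for q, sq in enumerate(rows):
            if len(sq) < len(sp) and sq < sp:
                rel.append((p, q))
    return rel


def _assemble(rows: list[frozenset[str]], model) -> GMatrix:
    rows = sorted(set(rows), key=_row_key)
    n = len(model.reactions)
    data_i, data_j = [], []
    for i, s in enumerate(rows):
        genes = {g for g in s if not is_nutrient_label(g)}
        uptakes = {g[len(NUTRIENT_PREFIX):] for g in s if is_nutrient_label(g)}
        for j, rid in enumerate(model.reactions):
            if rid in uptakes:
                data_i.append(i)
                data_j.append(j)
                continue
            expr = model.gprs.get(rid)
            if expr is not None and genes and not evaluate_gpr(expr, genes):
                data_i.append(i)
                data_j.append(j)
    mat = sparse.csr_matrix(
        (np.ones(len(data_i), dtype=np.int8), (data_i, data_j)),
        shape=(len(rows), n))
    return GMatrix(row_sets=rows, matrix=mat,
                   reaction_ids=list(model.reactions),
                   relations=_compute_relations(rows))


def build_g_matrix(model, max_set_size: int, **mds_kwargs) -> GMatrix:
    """Assemble G from the model's GPR rules.

    Rows are the union over reactions of each rule's minimal disabling
    sets up to ``max_set_size`` (larger disabling sets cannot appear in
    any cut set of that length), deduplicated; columns are filled by
    evaluating each row's knockout against EVERY reaction's rule.
    Identical rule strings share one enumeration.  Budget violations in
    the per-rule enumeration propagate with the reaction id attached.
    """
    rows: list[frozenset[str]] = []
    cache: dict[str, list[frozenset[str]]] = {}
    for rid in model.reactions:
        expr = model.gprs.get(rid)
        if expr is None:
            continue  # spontaneous/orphan reaction: never gene-knockable
        key = gpr_to_string(expr)
        if key not in cache:
            cache[key] = minimal_disabling_sets(
                expr, max_set_size, reaction_id=rid, **mds_kwargs)
        rows.extend(cache[key])
    g = _assemble(rows, model)
    logger.info("G matrix: %d rows x %d reactions, %d entries, %d relations",
                g.n_rows, len(g.reaction_ids), g.matrix.nnz, len(g.relations))
    return g


def extend_with_nutrients(g: GMatrix, model, nutrient_ids) -> GMatrix:
    """Add one pseudo-gene singleton row per nutrient uptake.

    Each nutrient (an exchange reaction with open uptake, lb < 0) gets a
    row labeled ``uptake:<exchange-id>`` whose single column is that
    exchange; pseudo-genes never mix with real genes inside one row.
    """
    nutrient_ids = list(nutrient_ids)
    if not nutrient_ids:
        return g
    exchanges = set(model.exchanges)
    for rid in nutrient_ids:
        if rid not in exchanges:
            raise ValueError(f"{rid!r} is not an exchange reaction")
        if model.lb[model.reaction_index(rid)] >= 0:
            raise ValueError(f"exchange {rid!r} has no open uptake (lb >= 0)")
    rows = list(g.row_sets) + [frozenset({NUTRIENT_PREFIX + rid})
                               for rid in nutrient_ids]
    return _assemble(rows, model)
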