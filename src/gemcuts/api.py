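"""Top-level pipelines: gene-, reaction-, and nutrient-aware cut sets.

`calculate_gene_mcs` chains the whole method — flux-consistency pruning,
G-matrix construction (optionally extended with nutrient pseudo-genes),
the dual MILP (optionally restricted to target genes), and the layered
enumeration — and returns verified minimal interventions.  Errors are
re-raised with the pipeline stage named in the message.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field

from .config import DEFAULTS, GemcutsError, log_defaults
from .enumeration import CutSetList, enumerate_cut_sets
from .gmatrix import build_g_matrix, extend_with_nutrients
from .milp import MILPOptions, apply_target_kos, build_gmcs_milp, build_mcs_milp
from .model_io import MetabolicModel, remove_blocked_reactions
from .solvers import SolverParams

logger = logging.getLogger("gemcuts.api")

__all__ = ["RunOptions", "StageError", "calculate_gene_mcs", "calculate_mcs"]


class StageError(GemcutsError):
    """Pipeline failure carrying the stage where it happened."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except GemcutsError as e:
        raise StageError(f"[stage {name}] {e}") from e
    except (ValueError, KeyError) as e:
        raise StageError(f"[stage {name}] {e}") from e


@dataclass
class RunOptions:
    """User-facing knobs of a cut-set run.

    ``b`` (growth threshold, flux units) defaults to ``growth_frac`` x
    the wild-type biomass optimum.  ``nutrients=None`` with
    ``is_nutrient=True`` means every exchange with open uptake.
    """

    max_length: int = 3
    max_solutions: int | float = float("inf")
    solver: str = "highs"
    target_kos: list[str] | None = None
    is_nutrient: bool = False
    nutrients: list[str] | None = None
    b: float | None = None
    time_limit: float = DEFAULTS.time_limit
    seed: int = 0
    threads: int = 1
    big_m: float = DEFAULTS.big_m
    remove_blocked: bool = True
    knockable: list[str] | None = None    # reaction-level only

    def __post_init__(self):
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        if self.b is not None and self.b <= 0:
            raise ValueError("growth threshold b must be > 0")

    def milp_options(self) -> MILPOptions:
        return MILPOptions(b=self.b, big_m=self.big_m,
                           knockable=self.knockable)

    def solver_params(self) -> SolverParams:
        return SolverParams(time_limit=self.time_limit, seed=self.seed,
                            threads=self.threads)


def _prune(model: MetabolicModel, options: RunOptions) -> MetabolicModel:
    if not options.remove_blocked:
        return model
    with _stage("remove_blocked_reactions"):
        return remove_blocked_reactions(model)


def calculate_gene_mcs(model: MetabolicModel,
                       options: RunOptions | None = None) -> CutSetList:
    """Genetic minimal cut sets up to ``options.max_length``.

    Pipeline: prune blocked reactions -> build G matrix (-> extend with
    nutrient pseudo-genes) -> build the dual MILP (-> restrict to target
    genes) -> layered enumeration.  Returns FBA-verified, irreducible
    gene (and pseudo-gene) sets sorted by (length, members); the list's
    ``complete`` flag is False when a time limit truncated the search.
    """
    options = options or RunOptions()
    log_defaults()
    work = _prune(model, options)
    with _stage("build_g_matrix"):
        g = build_g_matrix(work, max_set_size=options.max_length)
    if options.is_nutrient:
        with _stage("extend_with_nutrients"):
            nutrients = options.nutrients
            if nutrients is None:
                nutrients = [rid for rid in work.exchanges
                             if work.lb[work.reaction_index(rid)] < 0]
            g = extend_with_nutrients(g, work, nutrients)
    if g.n_rows == 0:
        # no gene set of size <= max_length disables any reaction, so no
        # gene cut set of that length can exist; the MILP itself refuses
        # zero-row G matrices
        logger.info("G matrix has no rows at max_length=%d: no solutions",
                    options.max_length)
        return CutSetList()
    with _stage("build_gmcs_milp"):
        spec = build_gmcs_milp(work, g, options.milp_options())
    if options.target_kos is not None:
        with _stage("apply_target_kos"):
            spec = apply_target_kos(spec, g, options.target_kos)
    with _stage("enumerate_cut_sets"):
        return enumerate_cut_sets(
            spec, work, g, max_length=options.max_length,
            max_solutions=options.max_solutions, solver=options.solver,
            seed=options.seed, params=options.solver_params())


def calculate_mcs(model: MetabolicModel,
                  options: RunOptions | None = None) -> CutSetList:
    """Reaction-level minimal cut sets (identity G over knockable reactions).

    Biomass and exchanges are excluded from the knockable set unless
    ``options.knockable`` overrides it.
    """
    options = options or RunOptions()
    log_defaults()
    work = _prune(model, options)
    with _stage("build_mcs_milp"):
        spec = build_mcs_milp(work, options.milp_options())
    if options.target_kos is not None:
        with _stage("apply_target_kos"):
            spec = apply_target_kos(spec, spec.gmatrix, options.target_kos)
    with _stage("enumerate_cut_sets"):
        return enumerate_cut_sets(
            spec, work, spec.gmatrix, max_length=options.max_length,
            max_solutions=options.max_solutions, solver=options.solver,
            seed=options.seed, params=options.solver_params())
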