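"""Central numeric tolerances, solver defaults, and logging.

Every floating tolerance used anywhere in the package lives in one
:class:`Config` object so that a run can be reproduced from a single
logged line.  Defaults are logged once, at first use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger("gemcuts")


@dataclass(frozen=True)
class Config:
    """Numeric and solver defaults.

    Attributes
    ----------
    flux_tol:
        Fluxes with magnitude below this are treated as zero
        (blocked-reaction FVA test, sink-feasibility checks).
    growth_frac:
        Default growth threshold ``b`` as a fraction of the wild-type
        biomass optimum, used when no absolute ``b`` is given.
    eps:
        Strictness margin of the dual-objective constraint: a knockout
        is certified lethal when the post-knockout biomass LP maximum
        is at most ``b - eps``.
    big_m:
        Big-M bound on the knockout-activation dual variables; wrong
        (too small) M silently loses solutions, so it is surfaced in
        logs whenever a MILP is built.
    int_tol:
        Integer feasibility tolerance forwarded to MILP backends;
        binaries are rounded at 0.5 on read-back and re-verified by
        FBA regardless.
    time_limit:
        Per-MILP-solve wall clock limit in seconds.
    bf_gene_limit:
        Up to this many distinct genes a GPR rule's minimal disabling
        sets are found by exact subset brute force; larger rules go
        through the artificial-network MILP route.
    work_budget:
        Cap on elementary operations (subset evaluations / LP calls)
        in combinatorial loops; exceeding it raises, never truncates.
    """

    flux_tol: float = 1e-7
    growth_frac: float = 1e-3
    eps: float = 1e-6
    big_m: float = 1e3
    int_tol: float = 1e-9
    time_limit: float = 300.0
    bf_gene_limit: int = 12
    work_budget: int = 2_000_000

    def with_overrides(self, **kw) -> "Config":
        return replace(self, **kw)


DEFAULTS = Config()

_logged = False


def log_defaults(cfg: Config = DEFAULTS) -> None:
    """Log the active tolerance set once per process."""
    global _logged
    if not _logged:
        logger.info("tolerances: %s", cfg)
        _logged = True


class BudgetExceededError(RuntimeError):
    """A combinatorial computation exceeded its configured work budget."""


class GemcutsError(Exception):
    """Base class for package errors."""
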