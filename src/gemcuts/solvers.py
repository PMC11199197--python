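"""Solver bridge: one MILP, interchangeable backends.

The same :class:`~gemcuts.milp.MILPSpec` runs unchanged on every
registered backend; the enumeration layer only ever talks to
``translate`` / ``add_constraint`` / ``solve``.  Two open-source
backends are provided:

``highs``
    HiGHS through ``scipy.optimize.milp``.
``glpk``
    GLPK through ``swiglpk`` (optional import; the backend registers
    itself as unavailable with an install hint when missing).

Neither backend supports native indicator constraints, so knockout
links always use the big-M translation — by contract a backend without
indicators must accept that translation and produce solutions that
verify identically.  Constraint addition is realized as a transparent
rebuild with identical semantics: handles keep the spec plus a list of
extra rows and re-translate on each solve.  Solver parameters
(time limit, gaps, integer tolerance, seed, threads) are plumbed into
each backend where it has the knob and recorded in the result metadata
either way.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULTS, GemcutsError
from .milp import LinearRow, MILPSpec

logger = logging.getLogger("gemcuts.solvers")

__all__ = ["SolverParams", "SolveResult", "SolverHandle", "Capabilities",
           "available_backends", "get_backend", "translate", "solve",
           "add_constraint", "SolverUnavailableError"]


class SolverUnavailableError(GemcutsError):
    """Requested backend cannot be loaded; message names the install hint."""


@dataclass(frozen=True)
class Capabilities:
    indicator_constraints: bool = False
    solution_pool: bool = False
    incremental: bool = False


@dataclass
class SolverParams:
    time_limit: float = DEFAULTS.time_limit   # seconds per solve
    seed: int = 0
    threads: int = 1
    mip_abs_gap: float = 0.0
    mip_rel_gap: float = 0.0
    int_tol: float = DEFAULTS.int_tol


@dataclass
class SolveResult:
    status: str                      # 'optimal' | 'infeasible' | 'time_limit' | 'error'
    objective: float | None = None
    x: np.ndarray | None = None
    backend: str = ""
    detail: object = None            # raw backend status / log excerpt


@dataclass
class SolverHandle:
    """Translated problem: spec + incrementally added rows."""

    spec: MILPSpec
    backend: str
    extra_rows: list[LinearRow] = field(default_factory=list)

    def all_rows(self) -> list[LinearRow]:
        return list(self.spec.rows) + self.extra_rows


def _assemble(handle: SolverHandle):
    from scipy import sparse

    spec = handle.spec
    rows = handle.all_rows()
    if rows:
        data, ri, ci = [], [], []
        for k, row in enumerate(rows):
            ri.extend([k] * len(row.idx))
            ci.extend(row.idx)
            data.extend(row.val)
        A = sparse.csr_matrix((data, (ri, ci)),
                              shape=(len(rows), spec.n_vars))
        rlb = np.array([r.lb for r in rows])
        rub = np.array([r.ub for r in rows])
    else:
        A = sparse.csr_matrix((0, spec.n_vars))
        rlb = rub = np.zeros(0)
    return A, rlb, rub


# ---------------------------------------------------------------------------
# HiGHS via scipy
# ---------------------------------------------------------------------------

class _HighsBackend:
    name = "highs"
    capabilities = Capabilities()

    @staticmethod
    def available() -> str | None:
        return None  # scipy is a hard dependency

    @staticmethod
    def solve(handle: SolverHandle, params: SolverParams) -> SolveResult:
        from scipy.optimize import Bounds, LinearConstraint, milp

        spec = handle.spec
        A, rlb, rub = _assemble(handle)
        constraints = (LinearConstraint(A, rlb, rub),) if A.shape[0] else ()
        opts = {"time_limit": params.time_limit,
                "mip_rel_gap": params.mip_rel_gap}
        res = milp(c=spec.obj, constraints=constraints,
                   integrality=spec.integer.astype(int),
                   bounds=Bounds(spec.lb, spec.ub), options=opts)
        # scipy/HiGHS status: 0 optimal, 1 iteration/time limit,
        # 2 infeasible, 3 unbounded, 4 other
        if res.status == 0:
            return SolveResult("optimal", float(res.fun), res.x,
                               "highs", res.message)
        if res.status == 1:
            return SolveResult("time_limit",
                               float(res.fun) if res.x is not None else None,
                               res.x, "highs", res.message)
        if res.status == 2:
            return SolveResult("infeasible", None, None, "highs", res.message)
        return SolveResult("error", None, None, "highs", res.message)


# ---------------------------------------------------------------------------
# GLPK via swiglpk
# ---------------------------------------------------------------------------

class _GlpkBackend:
    name = "glpk"
    capabilities = Capabilities()

    @staticmethod
    def available() -> str | None:
        try:
            import swiglpk  # noqa: F401
            return None
        except ImportError:
            return "pip install swiglpk"

    @staticmethod
    def solve(handle: SolverHandle, params: SolverParams) -> SolveResult:
        import swiglpk as glp

        spec = handle.spec
        A, rlb, rub = _assemble(handle)
        prob = glp.glp_create_prob()
        try:
            glp.glp_set_obj_dir(prob, glp.GLP_MIN)
            nrows, ncols = A.shape[0], spec.n_vars
            if nrows:
                glp.glp_add_rows(prob, nrows)
            glp.glp_add_cols(prob, ncols)

            def set_bnds(setter, i, lo, hi):
                lo_f, hi_f = math.isfinite(lo), math.isfinite(hi)
                if lo_f and hi_f:
                    kind = glp.GLP_FX if lo == hi else glp.GLP_DB
                elif lo_f:
                    kind = glp.GLP_LO
                elif hi_f:
                    kind = glp.GLP_UP
                else:
                    kind = glp.GLP_FR
                setter(prob, i, kind,
                       lo if lo_f else 0.0, hi if hi_f else 0.0)

            for k in range(nrows):
                set_bnds(glp.glp_set_row_bnds, k + 1, rlb[k], rub[k])
            for j in range(ncols):
                set_bnds(glp.glp_set_col_bnds, j + 1,
                         float(spec.lb[j]), float(spec.ub[j]))
                if spec.obj[j]:
                    glp.glp_set_obj_coef(prob, j + 1, float(spec.obj[j]))
                if spec.integer[j]:
                    glp.glp_set_col_kind(prob, j + 1, glp.GLP_IV)

            coo = A.tocoo()
            nnz = coo.nnz
            ia, ja = glp.intArray(nnz + 1), glp.intArray(nnz + 1)
            ar = glp.doubleArray(nnz + 1)
            for k, (i, j, v) in enumerate(zip(coo.row, coo.col, coo.data), 1):
                ia[k], ja[k], ar[k] = int(i) + 1, int(j) + 1, float(v)
            if nnz:
                glp.glp_load_matrix(prob, nnz, ia, ja, ar)

            parm = glp.glp_iocp()
            glp.glp_init_iocp(parm)
            parm.presolve = glp.GLP_ON
            parm.msg_lev = glp.GLP_MSG_OFF
            parm.tm_lim = max(1, int(params.time_limit * 1000))
            parm.tol_int = max(params.int_tol, 1e-12)
            if params.mip_rel_gap:
                parm.mip_gap = params.mip_rel_gap
            ret = glp.glp_intopt(prob, parm)
            if ret == glp.GLP_ETMLIM:
                return SolveResult("time_limit", None, None, "glpk", ret)
            if ret in (glp.GLP_ENOPFS, glp.GLP_ENODFS):
                return SolveResult("infeasible", None, None, "glpk", ret)
            if ret != 0:
                return SolveResult("error", None, None, "glpk",
                                   f"glp_intopt returned {ret}")
            status = glp.glp_mip_status(prob)
            if status in (glp.GLP_OPT, glp.GLP_FEAS):
                x = np.array([glp.glp_mip_col_val(prob, j + 1)
                              for j in range(ncols)])
                return SolveResult("optimal", float(glp.glp_mip_obj_val(prob)),
                                   x, "glpk", status)
            if status == glp.GLP_NOFEAS:
                return SolveResult("infeasible", None, None, "glpk", status)
            return SolveResult("error", None, None, "glpk", status)
        finally:
            glp.glp_delete_prob(prob)


_BACKENDS = {"highs": _HighsBackend, "glpk": _GlpkBackend}


def available_backends() -> list[str]:
    """Names of backends importable right now, deterministic order."""
    return [name for name, be in sorted(_BACKENDS.items())
            if be.available() is None]


def get_backend(name: str):
    try:
        be = _BACKENDS[name]
    except KeyError:
        raise SolverUnavailableError(
            f"unknown backend {name!r}; registered: {sorted(_BACKENDS)}"
        ) from None
    hint = be.available()
    if hint is not None:
        raise SolverUnavailableError(
            f"backend {name!r} is not installed (try: {hint})")
    return be


def translate(spec: MILPSpec, backend: str) -> SolverHandle:
    """Map a spec onto a backend problem handle (variables 1:1)."""
    get_backend(backend)  # raises early when unavailable
    return SolverHandle(spec=spec, backend=backend)


def add_constraint(handle: SolverHandle, row: LinearRow) -> SolverHandle:
    """Append a linear row; rebuild-on-solve keeps semantics identical."""
    if len(row.idx) and (row.idx.min() < 0
                         or row.idx.max() >= handle.spec.n_vars):
        raise ValueError("constraint references unknown variables")
    handle.extra_rows.append(row)
    return handle


def solve(handle: SolverHandle,
          params: SolverParams | None = None) -> SolveResult:
    """Solve; returns a status enum, never raises on infeasibility."""
    params = params or SolverParams()
    be = get_backend(handle.backend)
    logger.debug("solving on %s: %d vars, %d rows (%d added)",
                 handle.backend, handle.spec.n_vars,
                 len(handle.spec.rows) + len(handle.extra_rows),
                 len(handle.extra_rows))
    res = be.solve(handle, params)
    res.detail = {"raw": res.detail, "seed": params.seed,
                  "threads": params.threads,
                  "time_limit": params.time_limit}
    return res
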