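"""Constraint-based analysis core: FBA, FVA, flux consistency.

All three operate on the steady-state flux cone {v : S·v = 0, lb ≤ v ≤ ub}.
Linear programs are solved with the HiGHS solver through scipy.  A post-solve
residual check asserts ‖S·v‖∞ ≤ 1e−6 on every optimal solution.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import FluxResult, MetabolicModel

__all__ = ["fba", "fva", "consistent_subnetwork", "SolverError",
           "FEASIBILITY_TOL", "RESIDUAL_TOL", "DEFAULT_EPS"]

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-7
RESIDUAL_TOL = 1e-6
#: minimum flux magnitude considered "active"; scaled to default bounds of 1000
DEFAULT_EPS = 1e-4


class SolverError(RuntimeError):
    """Raised when the LP solver fails or a solution violates tolerances."""


_HIGHS_OPTS = {"presolve": True,
               "primal_feasibility_tolerance": FEASIBILITY_TOL,
               "dual_feasibility_tolerance": OPTIMALITY_TOL}


def _solve_lp(c: np.ndarray, model: MetabolicModel,
              extra_A_ub: Optional[sp.spmatrix] = None,
              extra_b_ub: Optional[np.ndarray] = None) -> FluxResult:
    """min c'v s.t. S v = 0, lb ≤ v ≤ ub (+ optional inequality rows)."""
    n = model.n_reactions
    if n == 0:
        return FluxResult(status="optimal", objective_value=0.0,
                          fluxes=np.empty(0))
    bounds = list(zip(model.lower_bounds, model.upper_bounds))
    if np.any(model.lower_bounds > model.upper_bounds):
        return FluxResult(status="infeasible")
    res = linprog(
        c,
        A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
        A_ub=extra_A_ub, b_ub=extra_b_ub,
        bounds=bounds, method="highs", options=_HIGHS_OPTS,
    )
    if res.status == 2:
        return FluxResult(status="infeasible")
    if res.status == 3:
        return FluxResult(status="unbounded")
    if res.status != 0:
        raise SolverError(f"LP solver failure: {res.message}")
    v = np.asarray(res.x)
    residual = np.abs(model.S @ v).max() if model.n_metabolites else 0.0
    if residual > RESIDUAL_TOL:
        raise SolverError(
            f"steady-state residual {residual:.2e} exceeds {RESIDUAL_TOL:.0e}")
    return FluxResult(status="optimal", objective_value=float(res.fun),
                      fluxes=v)


def fba(model: MetabolicModel,
        objective: Optional[np.ndarray] = None,
        direction: str = "max") -> FluxResult:
    """Flux balance analysis: optimise c'v over the steady-state flux cone.

    ``objective`` defaults to the model's own objective coefficients.
    The reported objective_value is c'v at the optimum (sign corrected for
    maximisation); ties between alternate optima are broken by the solver.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    c = np.asarray(objective if objective is not None
                   else model.objective_coeffs, dtype=float)
    if c.shape != (model.n_reactions,):
        raise ValueError(f"objective has shape {c.shape}, "
                         f"expected ({model.n_reactions},)")
    sign = -1.0 if direction == "max" else 1.0
    result = _solve_lp(sign * c, model)
    if result.ok:
        result.objective_value = sign * result.objective_value
    return result


def fva(model: MetabolicModel, objective_fraction: float = 0.0,
        reactions: Optional[Sequence[str]] = None,
        objective: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Flux variability analysis: per-reaction [min, max] flux.

    With ``objective_fraction`` > 0 the region is intersected with
    c'v ≥ fraction · (FBA optimum).  Returns a DataFrame indexed by
    reaction id with columns ``minimum`` and ``maximum``.
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must lie in [0, 1]")
    rids = list(reactions) if reactions is not None else list(model.reaction_ids)
    A_ub = b_ub = None
    if objective_fraction > 0.0:
        c = np.asarray(objective if objective is not None
                       else model.objective_coeffs, dtype=float)
        opt = fba(model, objective=c, direction="max")
        if not opt.ok:
            raise SolverError(
                f"FVA requires an FBA optimum; solver status {opt.status!r}")
        A_ub = sp.csr_matrix(-c[None, :])
        b_ub = np.array([-objective_fraction * opt.objective_value])
    mins, maxs = [], []
    for rid in rids:
        j = model.reaction_index(rid)
        c_j = np.zeros(model.n_reactions)
        c_j[j] = 1.0
        lo = _solve_lp(c_j, model, A_ub, b_ub)
        hi = _solve_lp(-c_j, model, A_ub, b_ub)
        if not lo.ok or not hi.ok:
            bad = lo if not lo.ok else hi
            raise SolverError(
                f"FVA subproblem for {rid!r} ended with status {bad.status!r}")
        mins.append(lo.objective_value)
        maxs.append(-hi.objective_value)
    return pd.DataFrame({"minimum": mins, "maximum": maxs}, index=rids)


def consistent_subnetwork(model: MetabolicModel,
                          eps: float = DEFAULT_EPS) -> set[str]:
    """Reactions that can carry |v| ≥ eps in some feasible flux distribution.

    The complement is the set of blocked reactions (at activity scale eps).
    Implemented as the per-reaction FVA oracle: reaction j is consistent iff
    fva_min_j ≤ −eps or fva_max_j ≥ +eps.  O(2N) LPs — correct by
    construction and fast enough for the model sizes this package targets.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if model.n_reactions == 0:
        return set()
    ranges = fva(model, objective_fraction=0.0)
    keep = (ranges["minimum"] <= -eps) | (ranges["maximum"] >= eps)
    return set(ranges.index[keep])
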