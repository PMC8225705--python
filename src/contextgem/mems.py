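"""Model extraction methods (MEMs).

Five algorithms that turn a reference genome-scale model plus reaction-level
expression evidence into a context-specific submodel:

* :func:`gimme` — keep the expressed reactions, minimise flux through
  lowly-expressed ones while sustaining a required metabolic functionality
  (RMF) at a fraction of its optimum;
* :func:`imat` — MILP that maximises the number of reactions whose flux
  activity agrees with their ternary expression state;
* :func:`fastcore` — smallest flux-consistent subnetwork containing a core
  set of reactions known to be active;
* :func:`init_extract` — MILP that trades per-reaction evidence weights
  against network feasibility, optionally relaxing strict steady state to a
  small net production of selected metabolites;
* :func:`tinit` — task-driven variant of INIT: the returned submodel must
  additionally be able to perform a list of metabolic tasks.

LPs and MILPs are solved with HiGHS through scipy; variable ordering is
fixed by the model's reaction order, so repeated runs with an identical
configuration return identical kept sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from . import cbm
from .model import MetabolicModel, extract_submodel

__all__ = ["ExtractionResult", "Task", "gimme", "imat", "fastcore",
           "init_extract", "tinit", "read_tasks", "DEFAULT_IMAT_EPS"]

#: minimum flux for a reaction to count as active in iMAT (1e-3 of the
#: conventional default bound magnitude 1000)
DEFAULT_IMAT_EPS = 1.0
_MILP_INT_TOL = 1e-6
_SUPPORT_TOL = 1e-7


@dataclass
class ExtractionResult:
    """Outcome of a model extraction: the kept reaction set, the induced
    context model, method-specific diagnostics, and the full configuration
    used (for reproducibility)."""

    method: str
    kept_reactions: set[str]
    context_model: MetabolicModel
    diagnostics: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.kept_reactions)


def _result(method: str, model: MetabolicModel, kept: set[str],
            diagnostics: dict, config: dict,
            model_id: Optional[str] = None) -> ExtractionResult:
    ctx = extract_submodel(model, kept,
                           model_id=model_id or f"{model.model_id}_{method}")
    return ExtractionResult(method=method, kept_reactions=set(kept),
                            context_model=ctx, diagnostics=diagnostics,
                            config=config)


# ---------------------------------------------------------------------------
# GIMME
# ---------------------------------------------------------------------------

def gimme(model: MetabolicModel,
          reaction_expr: Union[pd.Series, Mapping[str, float]],
          threshold: Union[float, pd.Series],
          rmf: Union[str, Mapping[str, float], np.ndarray],
          rmf_fraction: float = 0.9,
          eps: float = cbm.DEFAULT_EPS,
          model_id: Optional[str] = None) -> ExtractionResult:
    """Gene Inactivity Moderated by Metabolism and Expression.

    Stage 1 maximises the required metabolic functionality (RMF) giving the
    optimum z*.  Stage 2 minimises Σ_j w_j·|v_j| with w_j =
    max(threshold_j − expr_j, 0) for reactions with expression data and
    w_j = 0 for reactions without data, subject to steady state, bounds,
    and RMF ≥ rmf_fraction·z*.  The inconsistency score is the stage-2
    objective — the flux-weighted disagreement between expression and the
    metabolic objective.

    Kept reactions: those with expression ≥ threshold, plus those carrying
    |v| ≥ eps in the stage-2 optimum.

    ``rmf`` is a reaction id, a {reaction id: coefficient} mapping, or a
    coefficient vector; no silent default objective is applied.
    """
    if not 0.0 < rmf_fraction <= 1.0:
        raise ValueError("rmf_fraction must lie in (0, 1]")
    c = _objective_vector(model, rmf)
    expr = pd.Series(reaction_expr, dtype=float).reindex(model.reaction_ids)
    thr = (pd.Series(threshold, dtype=float).reindex(model.reaction_ids)
           if not np.isscalar(threshold)
           else pd.Series(float(threshold), index=model.reaction_ids))

    stage1 = cbm.fba(model, objective=c, direction="max")
    if not stage1.ok:
        raise cbm.SolverError(
            f"the RMF is {stage1.status} in the reference model; "
            f"choose a different required metabolic functionality")
    z_star = stage1.objective_value

    weights = (thr - expr).clip(lower=0.0).fillna(0.0).to_numpy()
    n = model.n_reactions
    # v = v+ - v-,  v± >= 0; minimise sum w (v+ + v-)
    lb, ub = model.lower_bounds, model.upper_bounds
    pos_ub = np.maximum(ub, 0.0)
    neg_ub = np.maximum(-lb, 0.0)
    c_lp = np.concatenate([weights, weights])
    S = model.S
    A_eq = sp.hstack([S, -S], format="csr")
    # net flux within [lb, ub] and RMF constraint
    I = sp.identity(n, format="csr")
    net = sp.hstack([I, -I], format="csr")
    A_ub = sp.vstack([net, -net, sp.csr_matrix(np.concatenate([-c, c])[None, :])],
                     format="csr")
    b_ub = np.concatenate([ub, -lb, [-rmf_fraction * z_star]])
    res = linprog(c_lp, A_eq=A_eq, b_eq=np.zeros(model.n_metabolites),
                  A_ub=A_ub, b_ub=b_ub,
                  bounds=list(zip(np.zeros(2 * n),
                                  np.concatenate([pos_ub, neg_ub]))),
                  method="highs")
    if res.status != 0:
        raise cbm.SolverError(f"GIMME stage-2 LP failed: {res.message}")
    v = res.x[:n] - res.x[n:]
    score = float(res.fun)

    expressed = set(expr.index[(expr >= thr) & expr.notna()])
    active = {model.reaction_ids[j] for j in np.flatnonzero(np.abs(v) >= eps)}
    kept = expressed | active
    config = {"method": "gimme", "threshold": _jsonable(threshold),
              "rmf": _jsonable(rmf), "rmf_fraction": rmf_fraction, "eps": eps}
    diags = {"inconsistency_score": score, "rmf_optimum": z_star,
             "stage2_fluxes": pd.Series(v, index=model.reaction_ids)}
    return _result("gimme", model, kept, diags, config, model_id)


# ---------------------------------------------------------------------------
# iMAT
# ---------------------------------------------------------------------------

def imat(model: MetabolicModel,
         ternary_calls: Union[pd.Series, Mapping[str, float]],
         eps: float = DEFAULT_IMAT_EPS,
         time_limit: Optional[float] = None,
         model_id: Optional[str] = None) -> ExtractionResult:
    """Integrative Metabolic Analysis Tool.

    ``ternary_calls`` maps reaction ids to −1 (lowly expressed), 0
    (moderate), +1 (highly expressed); missing/NaN is treated as moderate.
    The MILP maximises the number of agreements: a highly-expressed
    reaction agrees when it carries |v| ≥ eps (forward, or backward if
    reversible), a lowly-expressed reaction agrees when v = 0.

    Kept reactions: those with |v*| ≥ eps at the optimum, plus moderate /
    no-data reactions that remain unblocked in the submodel induced by the
    solution (they were never penalised, so one optimal vertex's inactivity
    is not evidence of absence).
    """
    calls = pd.Series(ternary_calls, dtype=float).reindex(
        model.reaction_ids).fillna(0.0)
    n = model.n_reactions
    lb, ub = model.lower_bounds, model.upper_bounds
    high = [j for j in range(n) if calls.iloc[j] > 0]
    low = [j for j in range(n) if calls.iloc[j] < 0]

    # variables: v (n) | y_fwd (per high) | y_bwd (per reversible high) | y0 (per low)
    n_yf = len(high)
    rev_high = [j for j in high if lb[j] < 0]
    n_yb = len(rev_high)
    n_y0 = len(low)
    n_var = n + n_yf + n_yb + n_y0
    off_yf = n
    off_yb = n + n_yf
    off_y0 = n + n_yf + n_yb
    yb_pos = {j: off_yb + k for k, j in enumerate(rev_high)}

    rows, cols, vals, con_lb, con_ub = [], [], [], [], []

    def add_row(entries, lo, hi):
        r = len(con_lb)
        for c_, v_ in entries:
            rows.append(r)
            cols.append(c_)
            vals.append(v_)
        con_lb.append(lo)
        con_ub.append(hi)

    S = model.S.tocoo()
    srow = {}
    for i, j, v in zip(S.row, S.col, S.data):
        srow.setdefault(i, []).append((j, v))
    for i in range(model.n_metabolites):
        add_row(srow.get(i, []), 0.0, 0.0)

    for k, j in enumerate(high):
        # y_fwd = 1  =>  v_j >= eps
        add_row([(j, 1.0), (off_yf + k, -(eps - lb[j]))], lb[j], np.inf)
        if j in yb_pos:
            # y_bwd = 1  =>  v_j <= -eps
            add_row([(j, 1.0), (yb_pos[j], ub[j] + eps)], -np.inf, ub[j])
            add_row([(off_yf + k, 1.0), (yb_pos[j], 1.0)], -np.inf, 1.0)
    for k, j in enumerate(low):
        # y0 = 1  =>  v_j = 0
        add_row([(j, 1.0), (off_y0 + k, float(lb[j]))], lb[j], np.inf)
        add_row([(j, 1.0), (off_y0 + k, float(ub[j]))], -np.inf, ub[j])

    A = sp.csc_matrix((vals, (rows, cols)), shape=(len(con_lb), n_var))
    c_obj = np.zeros(n_var)
    c_obj[n:] = -1.0  # maximise number of agreements
    integrality = np.zeros(n_var)
    integrality[n:] = 1
    var_lb = np.concatenate([lb, np.zeros(n_var - n)])
    var_ub = np.concatenate([ub, np.ones(n_var - n)])
    options = {"mip_rel_gap": 0.0}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(c_obj, constraints=LinearConstraint(A, con_lb, con_ub),
               integrality=integrality, bounds=Bounds(var_lb, var_ub),
               options=options)
    timed_out = res.status == 1  # iteration/time limit with incumbent
    if res.x is None:
        raise cbm.SolverError(
            f"iMAT MILP returned no incumbent solution: {res.message}")
    v = res.x[:n]
    objective = float(round(-res.fun))

    active = {model.reaction_ids[j] for j in np.flatnonzero(np.abs(v) >= eps - 1e-9)}
    moderate = {model.reaction_ids[j] for j in range(n) if calls.iloc[j] == 0}
    candidates = active | moderate
    sub = extract_submodel(model, candidates)
    unblocked = cbm.consistent_subnetwork(sub, eps=min(eps, cbm.DEFAULT_EPS))
    kept = active | (moderate & unblocked)

    config = {"method": "imat", "eps": eps, "time_limit": time_limit}
    diags = {"objective_value": objective,
             "activity": pd.Series(v, index=model.reaction_ids),
             "n_high": len(high), "n_low": len(low),
             "time_limit_hit": bool(timed_out)}
    return _result("imat", model, kept, diags, config, model_id)


# ---------------------------------------------------------------------------
# FASTCORE
# ---------------------------------------------------------------------------

def fastcore(model: MetabolicModel, core: Iterable[str],
             eps: float = cbm.DEFAULT_EPS,
             model_id: Optional[str] = None) -> ExtractionResult:
    """Smallest-seeking flux-consistent subnetwork containing every core
    reaction.

    The reference model must itself be flux-consistent (run
    :func:`contextgem.cbm.consistent_subnetwork` first) and every core
    reaction must be unblocked.  Implemented as the alternating two-LP
    expansion: one LP pushes as many unsupported core reactions as possible
    above eps, the next minimises the L1 norm of flux through non-core
    reactions while holding the supported core active; reversible core
    reactions that cannot be supported forward are retried with flipped
    bounds.
    """
    core = set(core)
    unknown = core - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"core reaction(s) not in model: {sorted(unknown)}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    config = {"method": "fastcore", "eps": eps, "core_size": len(core)}
    if not core:
        return _result("fastcore", model, set(), {"n_lp": 0}, config, model_id)

    work = model.copy()
    idx = {rid: j for j, rid in enumerate(model.reaction_ids)}
    irreversible = {rid for rid in model.reaction_ids
                    if model.lower_bounds[idx[rid]] >= 0}
    n_lp = 0

    def lp7(J: set[str]) -> Optional[np.ndarray]:
        # maximise sum_j min(v_j, eps) over j in J
        nonlocal n_lp
        n_lp += 1
        n = work.n_reactions
        Jl = sorted(J, key=idx.get)
        m = len(Jl)
        c = np.concatenate([np.zeros(n), -np.ones(m)])
        A_eq = sp.hstack([work.S, sp.csr_matrix((work.n_metabolites, m))],
                         format="csr")
        rows, cols, vals = [], [], []
        for k, rid in enumerate(Jl):
            rows.append(k); cols.append(n + k); vals.append(1.0)
            rows.append(k); cols.append(idx[rid]); vals.append(-1.0)
        A_ub = sp.csc_matrix((vals, (rows, cols)), shape=(m, n + m))
        bounds = list(zip(work.lower_bounds, work.upper_bounds)) + \
            [(0.0, eps)] * m
        res = linprog(c, A_eq=A_eq, b_eq=np.zeros(work.n_metabolites),
                      A_ub=A_ub, b_ub=np.zeros(m), bounds=bounds,
                      method="highs")
        return res.x[:n] if res.status == 0 else None

    def lp10(K: set[str], P: set[str]) -> Optional[np.ndarray]:
        # minimise sum_{p in P} |v_p| subject to v_k >= eps for k in K
        nonlocal n_lp
        n_lp += 1
        n = work.n_reactions
        Pl = sorted(P, key=idx.get)
        m = len(Pl)
        c = np.concatenate([np.zeros(n), np.ones(m)])
        A_eq = sp.hstack([work.S, sp.csr_matrix((work.n_metabolites, m))],
                         format="csr")
        rows, cols, vals, b = [], [], [], []
        for k, rid in enumerate(Pl):
            r = len(b)
            rows += [r, r]; cols += [idx[rid], n + k]; vals += [1.0, -1.0]
            b.append(0.0)
            r = len(b)
            rows += [r, r]; cols += [idx[rid], n + k]; vals += [-1.0, -1.0]
            b.append(0.0)
        A_ub = sp.csc_matrix((vals, (rows, cols)),
                             shape=(len(b), n + m)) if b else None
        lbv = work.lower_bounds.copy()
        for rid in K:
            lbv[idx[rid]] = max(lbv[idx[rid]], eps)
        bounds = list(zip(lbv, work.upper_bounds)) + [(0.0, np.inf)] * m
        res = linprog(c, A_eq=A_eq, b_eq=np.zeros(work.n_metabolites),
                      A_ub=A_ub, b_ub=np.zeros(len(b)) if b else None,
                      bounds=bounds, method="highs")
        return res.x[:n] if res.status == 0 else None

    def find_sparse_mode(J: set[str], P: set[str]) -> set[str]:
        if not J:
            return set()
        v = lp7(J)
        if v is None:
            return set()
        K = {rid for rid in J if v[idx[rid]] >= 0.99 * eps}
        if not K:
            return set()
        v = lp10(K, P)
        if v is None:
            return set()
        return {rid for rid in work.reaction_ids
                if abs(v[idx[rid]]) > _SUPPORT_TOL}

    all_rxns = set(model.reaction_ids)
    J = core & irreversible
    P = all_rxns - core
    A = find_sparse_mode(J, P)
    if J - A:
        missing = sorted(J - A)[0]
        raise ValueError(
            f"core reaction {missing!r} is blocked in the reference model")
    J = core - A
    flipped = False
    singleton = False
    while J:
        P = P - A
        target = {sorted(J, key=idx.get)[0]} if singleton else J
        A |= find_sparse_mode(target, P)
        if J & A:
            J -= A
            flipped = False
            singleton = False
        else:
            j_rev = target - irreversible
            if flipped or not j_rev:
                if singleton:
                    missing = sorted(J, key=idx.get)[0]
                    raise ValueError(
                        f"core reaction {missing!r} is blocked in the "
                        f"reference model")
                singleton = True
                flipped = False
            else:
                for rid in j_rev:
                    j = idx[rid]
                    lo, hi = work.lower_bounds[j], work.upper_bounds[j]
                    work.lower_bounds[j], work.upper_bounds[j] = -hi, -lo
                flipped = True
    return _result("fastcore", model, A, {"n_lp": n_lp}, config, model_id)


# ---------------------------------------------------------------------------
# INIT / tINIT
# ---------------------------------------------------------------------------

@dataclass
class Task:
    """A metabolic task: the model must produce the required outputs while
    consuming no metabolite except the allowed inputs.

    ``inputs`` maps metabolite id → maximum uptake rate; ``outputs`` maps
    metabolite id → minimum production rate.
    """

    task_id: str
    inputs: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, float] = field(default_factory=dict)


def read_tasks(path) -> list[Task]:
    """Read a task CSV with columns task_id, inputs, outputs, where inputs /
    outputs are ``metabolite:rate`` entries separated by ``;``."""
    df = pd.read_csv(path, dtype=str).fillna("")
    tasks = []
    for _, row in df.iterrows():
        def parse(cell: str) -> dict[str, float]:
            out = {}
            for part in str(cell).split(";"):
                part = part.strip()
                if part:
                    met, _, rate = part.rpartition(":")
                    out[met] = float(rate)
            return out
        tasks.append(Task(task_id=row["task_id"], inputs=parse(row["inputs"]),
                          outputs=parse(row["outputs"])))
    return tasks


def init_extract(model: MetabolicModel,
                 weights: Union[pd.Series, Mapping[str, float], np.ndarray],
                 metabolite_weights: Optional[Mapping[str, float]] = None,
                 production_allowance: float = 1e-2,
                 eps: float = cbm.DEFAULT_EPS,
                 tasks: Sequence[Task] = (),
                 time_limit: Optional[float] = None,
                 model_id: Optional[str] = None,
                 _method: str = "init") -> ExtractionResult:
    """Integrative Network Inference for Tissues.

    MILP over inclusion binaries z_j: maximise Σ_j w_j·z_j + Σ_i w^m_i·u_i,
    where z_j = 1 forces reaction j to carry |v_j| ≥ eps and z_j = 0 forces
    v_j = 0.  For metabolites with a positive weight w^m the strict steady
    state S·v = 0 is relaxed to S·v = u with a small net production
    u ∈ [0, production_allowance]; every other metabolite stays balanced.
    Every kept reaction therefore carries flux in the witness distribution.

    ``tasks`` (used by :func:`tinit`) adds, per task, a dedicated flux
    vector confined to the included reactions that must realise the task.
    Metabolites required as task outputs may be net-produced in the base
    distribution as well (unbounded allowance, no objective reward): a
    reaction kept solely to serve a production task would otherwise be
    unable to satisfy its own activity constraint.
    """
    w = pd.Series(weights, dtype=float)
    if isinstance(weights, np.ndarray):
        w = pd.Series(np.asarray(weights, dtype=float),
                      index=model.reaction_ids)
    w = w.reindex(model.reaction_ids).fillna(0.0)
    if not np.isfinite(w.to_numpy()).all():
        raise ValueError("INIT weights must be finite")
    if production_allowance < 0:
        raise ValueError("production_allowance must be ≥ 0")
    met_w = dict(metabolite_weights or {})
    unknown_mets = set(met_w) - set(model.metabolite_ids)
    if unknown_mets:
        raise KeyError(f"weighted metabolite(s) not in model: "
                       f"{sorted(unknown_mets)}")
    for t in tasks:
        bad = (set(t.inputs) | set(t.outputs)) - set(model.metabolite_ids)
        if bad:
            raise KeyError(
                f"task {t.task_id!r} requires metabolite(s) absent from the "
                f"model: {sorted(bad)}")
        if not _task_feasible(model, t):
            raise ValueError(
                f"task {t.task_id!r} is infeasible in the reference model")

    n = model.n_reactions
    lb, ub = model.lower_bounds, model.upper_bounds
    rev = [j for j in range(n) if lb[j] < 0]
    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    task_outputs = {m for t in tasks for m in t.outputs}
    weighted_mets = [m for m in model.metabolite_ids
                     if met_w.get(m, 0) > 0 or m in task_outputs]

    # variables: v+ (n) | v- (rev) | z (n, bin) | d (rev, bin) | u (weighted)
    #            | per task: v^t (n) and u^t (inputs+outputs of t)
    n_rev = len(rev)
    off_vm = n
    off_z = n + n_rev
    off_d = off_z + n
    off_u = off_d + n_rev
    n_base = off_u + len(weighted_mets)
    vm_pos = {j: off_vm + k for k, j in enumerate(rev)}
    d_pos = {j: off_d + k for k, j in enumerate(rev)}
    u_pos = {m: off_u + k for k, m in enumerate(weighted_mets)}

    task_offsets = []
    n_var = n_base
    for t in tasks:
        tmets = sorted(set(t.inputs) | set(t.outputs), key=met_index.get)
        task_offsets.append((n_var, n_var + n, tmets))
        n_var += n + len(tmets)

    rows, cols, vals, con_lb, con_ub = [], [], [], [], []

    def add_row(entries, lo, hi):
        r = len(con_lb)
        for c_, v_ in entries:
            rows.append(r); cols.append(c_); vals.append(v_)
        con_lb.append(lo); con_ub.append(hi)

    S = model.S.tocoo()
    srow: dict[int, list] = {}
    for i, j, v in zip(S.row, S.col, S.data):
        srow.setdefault(i, []).append((j, v))

    # steady state with optional net production: S(v+ - v-) - u = 0
    for i in range(model.n_metabolites):
        entries = []
        for j, v in srow.get(i, []):
            entries.append((j, v))
            if j in vm_pos:
                entries.append((vm_pos[j], -v))
        m = model.metabolite_ids[i]
        if m in u_pos:
            entries.append((u_pos[m], -1.0))
        add_row(entries, 0.0, 0.0)

    var_lb = np.zeros(n_var)
    var_ub = np.zeros(n_var)
    for j in range(n):
        var_ub[j] = max(ub[j], 0.0)
    for j in rev:
        var_ub[vm_pos[j]] = -lb[j]
    var_ub[off_z:off_z + n] = 1.0
    var_ub[off_d:off_d + n_rev] = 1.0
    big = 1e4
    for m in weighted_mets:
        var_ub[u_pos[m]] = big if m in task_outputs else production_allowance
    for j in range(n):
        zc = off_z + j
        fwd_cap = max(ub[j], 0.0)
        if fwd_cap > 0:
            add_row([(j, 1.0), (zc, -fwd_cap)], -np.inf, 0.0)  # v+ <= cap·z
        else:
            var_ub[j] = 0.0
        if j in vm_pos:
            add_row([(vm_pos[j], 1.0), (zc, lb[j])], -np.inf, 0.0)
            # direction binary keeps v+ and v- from both being positive
            if fwd_cap > 0:
                add_row([(j, 1.0), (d_pos[j], -fwd_cap)], -np.inf, 0.0)
            add_row([(vm_pos[j], 1.0), (d_pos[j], -lb[j])], -np.inf, -lb[j])
            add_row([(j, 1.0), (vm_pos[j], 1.0), (zc, -eps)], 0.0, np.inf)
        else:
            floor = max(eps, lb[j]) if lb[j] > 0 else eps
            add_row([(j, 1.0), (zc, -floor)], 0.0, np.inf)

    # task constraints: S v^t = u^t over included reactions only
    for t, (off_v, off_ut, tmets) in zip(tasks, task_offsets):
        ut_pos = {m: off_ut + k for k, m in enumerate(tmets)}
        for m in tmets:
            if m in t.outputs:
                var_lb[ut_pos[m]] = t.outputs[m]
                var_ub[ut_pos[m]] = big
            else:
                var_lb[ut_pos[m]] = -t.inputs[m]
                var_ub[ut_pos[m]] = 0.0
        for i in range(model.n_metabolites):
            entries = [(off_v + j, v) for j, v in srow.get(i, [])]
            m = model.metabolite_ids[i]
            if m in ut_pos:
                entries.append((ut_pos[m], -1.0))
            if entries:
                add_row(entries, 0.0, 0.0)
        for j in range(n):
            var_lb[off_v + j] = min(lb[j], 0.0)
            var_ub[off_v + j] = max(ub[j], 0.0)
            add_row([(off_v + j, 1.0), (off_z + j, -ub[j])], -np.inf, 0.0)
            add_row([(off_v + j, 1.0), (off_z + j, -lb[j])], 0.0, np.inf)

    c_obj = np.zeros(n_var)
    c_obj[off_z:off_z + n] = -w.to_numpy()
    for m in weighted_mets:
        c_obj[u_pos[m]] = -met_w.get(m, 0.0)
    integrality = np.zeros(n_var)
    integrality[off_z:off_d + n_rev] = 1

    A = sp.csc_matrix((vals, (rows, cols)), shape=(len(con_lb), n_var))
    options = {"mip_rel_gap": 0.0}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(c_obj, constraints=LinearConstraint(A, con_lb, con_ub),
               integrality=integrality, bounds=Bounds(var_lb, var_ub),
               options=options)
    if res.x is None:
        raise cbm.SolverError(f"INIT MILP infeasible or failed: {res.message}")
    z = res.x[off_z:off_z + n]
    kept = {model.reaction_ids[j] for j in range(n) if z[j] > 0.5}
    v = res.x[:n].copy()
    for j in rev:
        v[j] -= res.x[vm_pos[j]]
    config = {"method": _method, "production_allowance": production_allowance,
              "eps": eps, "n_tasks": len(tasks),
              "metabolite_weights": {k: float(vv) for k, vv in met_w.items()}}
    diags = {"objective_value": float(-res.fun),
             "fluxes": pd.Series(v, index=model.reaction_ids)}
    return _result(_method, model, kept, diags, config, model_id)


def tinit(model: MetabolicModel,
          weights: Union[pd.Series, Mapping[str, float], np.ndarray],
          tasks: Sequence[Task],
          metabolite_weights: Optional[Mapping[str, float]] = None,
          production_allowance: float = 1e-2,
          eps: float = cbm.DEFAULT_EPS,
          time_limit: Optional[float] = None,
          model_id: Optional[str] = None) -> ExtractionResult:
    """Task-driven INIT: the INIT objective under the hard constraint that
    every metabolic task remains feasible in the extracted submodel.  With
    an empty task list this reduces exactly to :func:`init_extract`."""
    return init_extract(model, weights,
                        metabolite_weights=metabolite_weights,
                        production_allowance=production_allowance, eps=eps,
                        tasks=list(tasks), time_limit=time_limit,
                        model_id=model_id, _method="tinit")


def _task_feasible(model: MetabolicModel, task: Task) -> bool:
    """Can the full model perform the task (LP feasibility)?"""
    n = model.n_reactions
    tmets = sorted(set(task.inputs) | set(task.outputs))
    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    k = len(tmets)
    A_eq = sp.hstack(
        [model.S,
         -sp.csc_matrix(([1.0] * k, ([met_index[m] for m in tmets], range(k))),
                        shape=(model.n_metabolites, k))], format="csr")
    bounds = list(zip(model.lower_bounds, model.upper_bounds))
    for m in tmets:
        if m in task.outputs:
            bounds.append((task.outputs[m], np.inf))
        else:
            bounds.append((-task.inputs[m], 0.0))
    res = linprog(np.zeros(n + k), A_eq=A_eq,
                  b_eq=np.zeros(model.n_metabolites), bounds=bounds,
                  method="highs")
    return res.status == 0


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _objective_vector(model: MetabolicModel,
                      rmf: Union[str, Mapping[str, float], np.ndarray]
                      ) -> np.ndarray:
    if isinstance(rmf, str):
        c = np.zeros(model.n_reactions)
        c[model.reaction_index(rmf)] = 1.0
        return c
    if isinstance(rmf, Mapping):
        c = np.zeros(model.n_reactions)
        for rid, coeff in rmf.items():
            c[model.reaction_index(rid)] = float(coeff)
        return c
    c = np.asarray(rmf, dtype=float)
    if c.shape != (model.n_reactions,):
        raise ValueError("RMF vector has wrong length")
    return c


def _jsonable(x):
    if isinstance(x, pd.Series):
        return {str(k): float(v) for k, v in x.items()}
    if isinstance(x, np.ndarray):
        return [float(v) for v in x]
    if isinstance(x, Mapping):
        return {str(k): float(v) for k, v in x.items()}
    return x
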