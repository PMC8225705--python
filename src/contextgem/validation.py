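"""Brute-force reference implementations for validating the extraction MILPs.

Each function here solves the same problem as its production counterpart by
exhaustive enumeration over tiny networks (≤ ~12 reactions), using nothing
but LP feasibility checks.  They are deliberately independent of the MILP
formulations in :mod:`contextgem.mems` so that agreement between the two
routes is evidence of correctness, not of shared bugs.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from . import cbm
from .model import MetabolicModel, extract_submodel
from .synthetic import make_toy_model

__all__ = ["imat_objective_bruteforce", "minimal_consistent_superset",
           "init_bruteforce", "random_oracle_fixture"]


def _feasible(model: MetabolicModel, lb: np.ndarray, ub: np.ndarray) -> bool:
    if np.any(lb > ub):
        return False
    res = linprog(np.zeros(model.n_reactions), A_eq=model.S,
                  b_eq=np.zeros(model.n_metabolites),
                  bounds=list(zip(lb, ub)), method="highs")
    return res.status == 0


def imat_objective_bruteforce(model: MetabolicModel,
                              ternary_calls: Mapping[str, float],
                              eps: float) -> int:
    """Maximum number of expression-consistent reactions, by enumeration.

    For every assignment of {active forward, active backward, not rewarded}
    to the highly-expressed reactions and {zero, not rewarded} to the
    lowly-expressed ones, an LP feasibility check decides whether a flux
    distribution realises it; the best realisable reward count is returned.
    """
    calls = pd.Series(ternary_calls, dtype=float).reindex(
        model.reaction_ids).fillna(0.0)
    idx = {r: j for j, r in enumerate(model.reaction_ids)}
    high = [r for r in model.reaction_ids if calls[r] > 0]
    low = [r for r in model.reaction_ids if calls[r] < 0]
    best = 0
    # per high reaction: 0 = unrewarded, 1 = forward ≥ eps, 2 = backward ≤ -eps
    high_options = []
    for r in high:
        opts = [0, 1]
        if model.lower_bounds[idx[r]] < 0:
            opts.append(2)
        high_options.append(opts)
    for h_assign in itertools.product(*high_options):
        reward_h = sum(1 for a in h_assign if a != 0)
        for l_bits in itertools.product([0, 1], repeat=len(low)):
            reward = reward_h + sum(l_bits)
            if reward <= best:
                continue
            lb = model.lower_bounds.copy()
            ub = model.upper_bounds.copy()
            for r, a in zip(high, h_assign):
                j = idx[r]
                if a == 1:
                    lb[j] = max(lb[j], eps)
                elif a == 2:
                    ub[j] = min(ub[j], -eps)
            for r, b in zip(low, l_bits):
                if b:
                    j = idx[r]
                    lb[j] = max(lb[j], 0.0)
                    ub[j] = min(ub[j], 0.0)
            if _feasible(model, lb, ub):
                best = reward
    return best


def _fully_consistent(model: MetabolicModel, eps: float) -> bool:
    if model.n_reactions == 0:
        return True
    return len(cbm.consistent_subnetwork(model, eps=eps)) == model.n_reactions


def minimal_consistent_superset(model: MetabolicModel, core: Iterable[str],
                                eps: float = cbm.DEFAULT_EPS
                                ) -> Optional[set[str]]:
    """Smallest flux-consistent subnetwork containing the core, by
    enumerating supersets in order of increasing size.  Returns None when
    no consistent superset exists (blocked core)."""
    core = set(core)
    if not core:
        return set()
    others = [r for r in model.reaction_ids if r not in core]
    for extra in range(len(others) + 1):
        for combo in itertools.combinations(others, extra):
            keep = core | set(combo)
            sub = extract_submodel(model, keep)
            if _fully_consistent(sub, eps):
                return keep
    return None


def init_bruteforce(model: MetabolicModel, weights: Mapping[str, float],
                    eps: float = cbm.DEFAULT_EPS
                    ) -> tuple[float, list[frozenset]]:
    """Best INIT objective and all optimal kept sets, by enumerating every
    inclusion pattern (irreversible networks, strict steady state).

    A pattern is realisable when one flux distribution carries v ≥ eps on
    every included reaction and v = 0 on every excluded one.
    """
    if bool(np.any(model.lower_bounds < 0)):
        raise ValueError("brute-force INIT oracle assumes an irreversible "
                         "network")
    w = pd.Series(weights, dtype=float).reindex(model.reaction_ids).fillna(0.0)
    rxns = list(model.reaction_ids)
    best = 0.0  # the empty network is always realisable with objective 0
    best_sets = [frozenset()]
    for bits in itertools.product([0, 1], repeat=len(rxns)):
        if not any(bits):
            continue
        keep = {r for r, b in zip(rxns, bits) if b}
        obj = float(sum(w[r] for r in keep))
        if obj < best - 1e-12:
            continue
        lb = model.lower_bounds.copy()
        ub = model.upper_bounds.copy()
        for j, (r, b) in enumerate(zip(rxns, bits)):
            if b:
                lb[j] = max(lb[j], eps)
            else:
                lb[j] = max(lb[j], 0.0)
                ub[j] = min(ub[j], 0.0)
        if _feasible(model, lb, ub):
            if obj > best + 1e-12:
                best = obj
                best_sets = [frozenset(keep)]
            else:
                best_sets.append(frozenset(keep))
    return best, best_sets


def random_oracle_fixture(seed: int, allow_reversible: bool = True):
    """Small random network + random expression evidence for oracle tests.

    Returns (model, ternary_calls, weights, core): a 2-3 pathway × 1-2
    branch toy network (6-12 reactions), ternary calls with 2-3 high and
    1-3 low reactions, INIT-style weights in [-1, 1], and a small core set.
    With ``allow_reversible`` a few internal branches may run backwards.
    """
    rng = np.random.default_rng(seed)
    model = make_toy_model(int(rng.integers(2, 4)), int(rng.integers(1, 3)),
                           seed=seed, model_id=f"fixture_{seed}")
    internal = [r for r in model.reaction_ids if not r.startswith("EX_")]
    if allow_reversible and len(internal) > 2:
        for r in rng.choice(internal, size=rng.integers(0, 3), replace=False):
            j = model.reaction_index(r)
            model.lower_bounds[j] = -model.upper_bounds[j]
    n_high = int(rng.integers(2, 4))
    n_low = int(rng.integers(1, 4))
    picks = rng.choice(model.reaction_ids,
                       size=min(n_high + n_low, model.n_reactions),
                       replace=False)
    calls = pd.Series(0.0, index=model.reaction_ids)
    calls[picks[:n_high]] = 1.0
    calls[picks[n_high:]] = -1.0
    weights = pd.Series(rng.uniform(-1.0, 1.0, model.n_reactions),
                        index=model.reaction_ids).round(3)
    core = set(rng.choice(internal, size=min(2, len(internal)),
                          replace=False))
    return model, calls, weights, core
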