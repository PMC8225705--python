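"""Differential-reaction detection and subsystem enrichment.

Across two groups of context-specific models, a reaction is differentially
regulated when its mean sampled flux correlates with the group indicator
(Spearman rank correlation, midranks for ties, two-sided p).  Reactions
absent from a model contribute a mean flux of 0 — in an extracted model,
absence is the strongest form of inactivity.

Subsystems are then tested for enrichment of up- (or down-) regulated
reactions with the one-tailed hypergeometric test, and the subsystem-level
p-values are adjusted with the Benjamini–Hochberg step-up procedure within
each comparison.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["differential_reactions", "subsystem_enrichment", "bh_adjust"]


def differential_reactions(mean_flux_table: pd.DataFrame,
                           group_labels: Union[pd.Series, Mapping[str, str]],
                           alpha: float = 0.05) -> pd.DataFrame:
    """Spearman-based differential reactions between two model groups.

    ``mean_flux_table``: model × reaction mean fluxes (NaN = reaction
    absent from that model → treated as 0).  ``group_labels`` maps each
    model id to one of exactly two group names; the lexicographically
    second group is encoded 1, so rho > 0 means higher flux in that group
    ("up" direction).

    Returns a per-reaction DataFrame with columns rho, p_value, direction
    (up / down / ns), n_a, n_b.
    """
    labels = pd.Series(group_labels).reindex(mean_flux_table.index)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValueError(f"model(s) without a group label: {missing}")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    indicator = (labels == groups[1]).astype(float).to_numpy()
    n_a = int((labels == groups[0]).sum())
    n_b = int((labels == groups[1]).sum())
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs at least 2 models")

    table = mean_flux_table.fillna(0.0)
    rows = []
    for rid in table.columns:
        x = table[rid].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            rows.append((rid, np.nan, np.nan, "ns", True))
            continue
        rho, p = stats.spearmanr(x, indicator)
        sig = p < alpha
        direction = "up" if (sig and rho > 0) else ("down" if (sig and rho < 0)
                                                    else "ns")
        rows.append((rid, float(rho), float(p), direction, False))
    out = pd.DataFrame(rows, columns=["reaction", "rho", "p_value",
                                      "direction", "constant"])
    out = out.set_index("reaction")
    out["n_a"] = n_a
    out["n_b"] = n_b
    out.attrs["groups"] = groups
    n_const = int(out["constant"].sum())
    if n_const:
        logger.info("%d reaction(s) with constant flux across models: "
                    "correlation undefined, reported ns", n_const)
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j ≥ i} (p_(j)·m/j) over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def subsystem_enrichment(diff: pd.DataFrame,
                         subsystem_map: Mapping[str, str],
                         direction: str = "up",
                         alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric enrichment of subsystems among differential reactions.

    Universe N = reactions in ``diff`` that carry a (non-empty) subsystem
    label; K = subsystem size within the universe; n = number of
    significant reactions in the requested direction; k = their overlap
    with the subsystem.  p = P[X ≥ k], X ~ Hypergeom(N, K, n); adjusted by
    Benjamini–Hochberg across the subsystems of this comparison.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    labelled = {rid: sub for rid, sub in subsystem_map.items()
                if sub and rid in diff.index}
    universe = list(labelled)
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe: no labelled reactions in the table")
    skipped = {sub for rid, sub in subsystem_map.items()
               if sub and rid not in diff.index}
    for sub in sorted(skipped - set(labelled.values())):
        logger.info("subsystem %r has no reactions in the universe; skipped",
                    sub)
    sig = set(diff.index[diff["direction"] == direction]) & set(universe)
    n = len(sig)
    subsystems = sorted(set(labelled.values()))
    rows = []
    for sub in subsystems:
        members = {rid for rid, s in labelled.items() if s == sub}
        K = len(members)
        k = len(members & sig)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((sub, direction, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["subsystem", "direction", "k", "K",
                                      "n", "N", "p_value"])
    out["adjusted_p"] = bh_adjust(out["p_value"]) if len(out) else []
    out["significant"] = out["adjusted_p"] < alpha
    return out.set_index("subsystem")
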