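"""Reproducible end-to-end benchmark on the canonical synthetic study.

Runs the full FASTCORE-based workflow — per-sample thresholding at the 80th
per-sample percentile, GPR mapping, extraction, presence-matrix PCA with
factor-variance attribution, ACHR sampling, Spearman differential reactions
and hypergeometric subsystem enrichment — on the planted-effect study from
:func:`contextgem.synthetic.make_study`, and reports whether the planted
factor and subsystem were recovered.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import cbm, compare, enrichment, sampling
from .pipeline import extract_per_sample
from .synthetic import make_study

__all__ = ["recovery_study", "typeI_rejection_rate"]


def recovery_study(seed: int, n_samples: int = 1000, burn_in: int = 1000,
                   thinning: int = 2, percentile: float = 80.0,
                   chain_seed: Optional[int] = None) -> dict:
    """One seed of the planted-effect recovery benchmark.

    ``seed`` selects the study instance (toy network topology, GPR draws,
    planted expression matrix); ``chain_seed`` (default: derived from
    ``seed``) drives the ACHR sampling chains, the only stochastic stage of
    the analysis itself.  Returns a dict with the variance explained by
    each factor on PC1, the top-ranked factor, the planted subsystem's best
    BH-adjusted enrichment p-value, and whether it is the minimum of its
    comparison.
    """
    if chain_seed is None:
        chain_seed = seed * 1000
    model, expr, truth = make_study(seed=seed)
    planted = truth["effects"][0]
    factor, subsystem = planted["factor"], planted["subsystem"]

    consistent = cbm.consistent_subnetwork(model)
    results = extract_per_sample(model, expr, {"method": "fastcore"},
                                 {"rule": "per_sample", "p": percentile},
                                 consistent=consistent)
    sets = {s: r.kept_reactions for s, r in results.items()}
    pm = compare.presence_matrix(sets, model, model_factors=expr.factors)
    scores, fractions = compare.pca_reactions(pm)
    vbf = {f: compare.variance_by_factor(scores["PC1"], expr.factors[f])
           for f in expr.factors.columns}
    top_factor = max(vbf, key=vbf.get)

    means = {}
    for i, (s, r) in enumerate(results.items()):
        if r.context_model.n_reactions == 0:
            means[s] = pd.Series(dtype=float)
            continue
        fs = sampling.achr_sample(r.context_model, n_samples=n_samples,
                                  seed=chain_seed + i, burn_in=burn_in,
                                  thinning=thinning)
        means[s] = sampling.mean_fluxes(fs)
    table = pd.DataFrame(means).T.fillna(0.0)
    diff = enrichment.differential_reactions(table, expr.factors[factor])
    submap = model.subsystem_map()
    planted_p = np.inf
    overall_min = np.inf
    for direction in ("up", "down"):
        enr = enrichment.subsystem_enrichment(diff, submap,
                                              direction=direction)
        overall_min = min(overall_min, float(enr["adjusted_p"].min()))
        if subsystem in enr.index:
            planted_p = min(planted_p, float(enr.loc[subsystem, "adjusted_p"]))
    return {
        "seed": seed,
        "variance_by_factor_pc1": vbf,
        "top_factor": top_factor,
        "planted_factor": factor,
        "top_factor_is_planted": top_factor == factor,
        "pc1_variance_fraction": float(fractions[0]),
        "planted_adjusted_p": planted_p,
        "planted_enriched": planted_p < 0.05,
        "planted_is_minimum": planted_p <= overall_min + 1e-12,
    }


def typeI_rejection_rate(n_reps: int = 1000, seed: int = 0, N: int = 40,
                         K: int = 8, n_sig: int = 10,
                         alpha: float = 0.05) -> float:
    """Empirical type-I error of the hypergeometric subsystem test.

    Draws a uniformly random significant set of size ``n_sig`` from a
    universe of ``N`` reactions (one subsystem of size ``K``) and records
    how often the subsystem's raw p-value falls below ``alpha``.  The test
    is discrete and therefore conservative: the rate should not exceed
    alpha by more than Monte-Carlo noise.
    """
    from scipy import stats
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        sig = rng.choice(N, size=n_sig, replace=False)
        k = int((sig < K).sum())  # first K reactions form the subsystem
        p = stats.hypergeom.sf(k - 1, N, K, n_sig)
        if p < alpha:
            rejections += 1
    return rejections / n_reps
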