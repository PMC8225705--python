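"""Synthetic reference models and expression matrices with planted effects.

The generator emulates the shape of a real study — a flux-consistent
reference network whose reactions carry subsystem labels and GPR rules,
plus a normalized gene × sample expression matrix over a multi-factor
design (e.g. genotype × gender × diet) with effects planted at the gene
level so the GPR mapping is exercised end to end.

Topology: parallel pathways from a shared uptake to a shared secretion.
Each pathway is one subsystem; because pathways are parallel, an extraction
method can genuinely drop unaffected ones, which is what makes planted
effects recoverable.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .model import MetabolicModel, build_model

__all__ = ["make_toy_model", "make_expression", "full_factorial_design",
           "make_study", "DEFAULT_FACTOR_LEVELS"]

#: the default 2×2×3 study design: genotype × gender × diet
DEFAULT_FACTOR_LEVELS = {
    "genotype": ("WT", "KO"),
    "gender": ("F", "M"),
    "diet": ("LFnC", "HFnC", "HFC"),
}


def make_toy_model(n_core_paths: int = 3, n_branch_reactions: int = 4,
                   subsystem_labels: Optional[Sequence[str]] = None,
                   seed: int = 0, uptake_bound: float = 10.0,
                   internal_bound: float = 1000.0,
                   model_id: Optional[str] = None) -> MetabolicModel:
    """Flux-consistent toy network of parallel labelled pathways.

    ``n_core_paths`` pathways (one subsystem each) run in parallel from a
    shared uptake metabolite A to a shared secretion metabolite Z; each
    pathway consists of ``n_branch_reactions`` parallel branch reactions
    A → Z.  Because branches are parallel — not chained — each reaction can
    enter or leave an extracted model independently of its neighbours,
    which is what keeps background presence variation incoherent and a
    planted whole-subsystem effect coherent.  Every reaction gets a GPR
    over 1–3 genes with AND/OR structure (genes are pathway-specific so a
    planted subsystem effect propagates through the mapping).  The network
    has no blocked reactions by construction.
    """
    if n_core_paths < 1 or n_branch_reactions < 1:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    if subsystem_labels is None:
        subsystem_labels = [f"pathway_{p + 1}" for p in range(n_core_paths)]
    if len(subsystem_labels) != n_core_paths:
        raise ValueError("need one subsystem label per pathway")

    reactions = []
    gprs: dict[str, str] = {}
    subsystems: dict[str, str] = {}
    # exchange reactions carry no subsystem label, as in real GEMs:
    # they are transport plumbing, not a metabolic subsystem, and they give
    # the enrichment universe its unlabelled class
    reactions.append(("EX_uptake", {"A": 1.0}, 0.0, uptake_bound))
    for p in range(n_core_paths):
        sub = subsystem_labels[p]
        for i in range(n_branch_reactions):
            rid = f"{sub}_r{i + 1}"
            reactions.append((rid, {"A": -1.0, "Z": 1.0}, 0.0, internal_bound))
            subsystems[rid] = sub
            n_genes = int(rng.integers(1, 4))
            genes = [f"g_{sub}_{i + 1}_{k}" for k in range(n_genes)]
            if n_genes == 1:
                gprs[rid] = genes[0]
            elif n_genes == 2:
                gprs[rid] = f"{genes[0]} and {genes[1]}"
            else:
                # one complex of two subunits, one isoenzyme alternative
                gprs[rid] = f"({genes[0]} and {genes[1]}) or {genes[2]}"
    reactions.append(("EX_secretion", {"Z": -1.0}, 0.0, internal_bound))
    return build_model(reactions, gprs=gprs, subsystems=subsystems,
                       objective={"EX_secretion": 1.0},
                       model_id=model_id or f"toy_{n_core_paths}x{n_branch_reactions}")


def full_factorial_design(
        factor_levels: Mapping[str, Sequence[str]] = DEFAULT_FACTOR_LEVELS,
        n_replicates: int = 1) -> pd.DataFrame:
    """Sample × factor design table covering every level combination.

    The default 2×2×3 design yields 12 samples named S01..S12.
    """
    names = list(factor_levels)
    combos = list(itertools.product(*(factor_levels[f] for f in names)))
    combos = combos * n_replicates
    idx = [f"S{i + 1:02d}" for i in range(len(combos))]
    return pd.DataFrame(combos, columns=names, index=idx)


def make_expression(model: MetabolicModel,
                    design: Optional[pd.DataFrame] = None,
                    effects: Sequence[Mapping] = (),
                    noise_sd: float = 0.3, seed: int = 0,
                    baseline_mean: float = 2.0,
                    baseline_sd: float = 0.5
                    ) -> tuple[ExpressionMatrix, dict]:
    """Expression matrix over a factor design with gene-level planted effects.

    Each gene's baseline is drawn once from Normal(baseline_mean,
    baseline_sd) on the log scale (i.e. LogNormal on the raw scale).  Each
    effect is a mapping with keys ``factor``, ``level``, ``subsystem``,
    ``log_effect``: all genes of the affected subsystem are shifted by
    log_effect in samples carrying that factor level.  I.i.d. Gaussian
    noise (sd = noise_sd) is added on the log scale.

    Returns the matrix plus a truth record listing affected genes,
    reactions, and subsystems per effect.
    """
    if design is None:
        design = full_factorial_design()
    rng = np.random.default_rng(seed)
    sub_genes: dict[str, set[str]] = {}
    sub_rxns: dict[str, set[str]] = {}
    for j, sub in enumerate(model.subsystems):
        g = model.gpr_rules[j]
        sub_rxns.setdefault(sub, set()).add(model.reaction_ids[j])
        if g is not None:
            sub_genes.setdefault(sub, set()).update(g.genes())
    genes = list(model.gene_ids)
    samples = list(design.index)
    base = rng.normal(baseline_mean, baseline_sd, size=len(genes))
    values = np.tile(base[:, None], (1, len(samples)))

    truth = {"effects": [], "seed": seed, "noise_sd": noise_sd}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for eff in effects:
        factor, level = eff["factor"], eff["level"]
        sub, size = eff["subsystem"], float(eff["log_effect"])
        if sub not in sub_genes:
            raise KeyError(f"unknown subsystem {sub!r} (no genes)")
        if factor not in design.columns:
            raise KeyError(f"unknown factor {factor!r}")
        hit_samples = [s for s in samples if design.loc[s, factor] == level]
        rows = [gene_pos[g] for g in sorted(sub_genes[sub])]
        cols = [samples.index(s) for s in hit_samples]
        for i in rows:
            values[i, cols] += size
        truth["effects"].append({
            "factor": factor, "level": level, "subsystem": sub,
            "log_effect": size,
            "genes": sorted(sub_genes[sub]),
            "reactions": sorted(sub_rxns.get(sub, set())),
            "samples": hit_samples,
        })
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(values=matrix, factors=design.copy()), truth


def make_study(seed: int = 0, n_core_paths: int = 6,
               n_branch_reactions: int = 6, factor: str = "gender",
               level: str = "M", subsystem: str = "pathway_2",
               log_effect: float = 2.0, noise_sd: float = 0.3
               ) -> tuple[MetabolicModel, ExpressionMatrix, dict]:
    """The canonical synthetic study: a 12-sample 2×2×3 factorial design
    with one knockout-scale effect planted on one subsystem.

    Defaults encode the benchmark conditions: 6 pathways × 6 parallel
    branch reactions (38 reactions, ~70 genes), a 4-fold (log-effect 2)
    shift of the planted subsystem's genes in one level of one binary
    factor, and per-(gene, sample) noise of 0.3 on the log scale.  The
    planted block of 6 reactions is sized so that, after Benjamini–Hochberg
    adjustment across subsystems, the planted enrichment is detectable from
    12 samples; the per-sample percentile cutoff adapts upward in
    effect-carrying samples, which is why the planted shift must clear the
    within-sample spread by a wide margin.
    """
    model = make_toy_model(n_core_paths, n_branch_reactions, seed=seed)
    effects = [{"factor": factor, "level": level, "subsystem": subsystem,
                "log_effect": log_effect}]
    expr, truth = make_expression(model, effects=effects, noise_sd=noise_sd,
                                  seed=seed)
    return model, expr, truth
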