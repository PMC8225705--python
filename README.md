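# contextgem

Guided extraction and analysis of **context-specific genome-scale metabolic
models** (GEMs) from gene-expression data.

A genome-scale model collects every known metabolic reaction of an organism
as a stoichiometric matrix *S* (metabolites × reactions) with flux bounds
and gene–protein–reaction (GPR) rules. Not every reaction is active in
every tissue or condition: a *context-specific* model is a submodel in
which inactive reactions have been removed, guided by omics evidence. Which
extraction algorithm to use, and how to turn continuous expression into
activity calls, are consequential choices — different methods and
thresholds produce very different models. `contextgem` implements the full
guided workflow for making that choice defensibly:

1. **Constraint-based core** — flux balance analysis (FBA), flux
   variability analysis (FVA) and flux-consistency testing on the
   steady-state cone {v : S·v = 0, lb ≤ v ≤ ub}.
2. **Expression integration** — per-sample and per-gene percentile (or
   mean) thresholds; ternary low/moderate/high calls; GPR mapping with
   AND = min, OR = max.
3. **Five extraction methods (MEMs)** — GIMME, iMAT, FASTCORE, INIT and
   tINIT, built on the HiGHS LP/MILP solver.
4. **Model comparison & selection** — reaction-presence matrices (constant
   rows removed, rows zero-centered), pairwise Jaccard indices, PCA on
   reactions, the percentage of a component's variance explained by an
   experimental factor (100·max²|r| over all level orderings), and t-SNE.
5. **Analysis** — artificial-centering hit-and-run (ACHR) flux sampling,
   Spearman-based differential reactions between model groups, and
   hypergeometric subsystem enrichment with Benjamini–Hochberg control.

It ships a synthetic-study generator (flux-consistent toy networks with
labelled subsystems and planted multi-factor expression effects) so the
entire pipeline is testable without downloading any dataset, plus a
config-driven CLI.

## Worked example

```python
import contextgem as cg
from contextgem.synthetic import make_study
from contextgem.pipeline import extract_per_sample

# 12-sample genotype × gender × diet study with a 4-fold effect planted
# on the genes of one subsystem ("pathway_2") in male samples
model, expr, truth = make_study(seed=0)
print(model)
# MetabolicModel('toy_6x6': 38 reactions, 2 metabolites, 73 genes)

consistent = cg.consistent_subnetwork(model)     # blocked-reaction check
results = extract_per_sample(model, expr, {"method": "fastcore"},
                             {"rule": "per_sample", "p": 80},
                             consistent=consistent)
print({s: r.size for s, r in results.items()})
# {'S01': 7, 'S02': 8, 'S03': 5, 'S04': 9, 'S05': 9, 'S06': 9,
#  'S07': 9, 'S08': 10, 'S09': 7, 'S10': 11, 'S11': 9, 'S12': 10}

sets = {s: r.kept_reactions for s, r in results.items()}
pm = cg.presence_matrix(sets, model, model_factors=expr.factors)
scores, fractions = cg.pca_reactions(pm)
print(f"PC1 variance fraction: {fractions[0]:.2f}")        # 0.51
for factor in expr.factors.columns:
    v = cg.variance_by_factor(scores["PC1"], expr.factors[factor])
    print(f"variance explained by {factor} on PC1: {v:.1f}%")
# genotype 0.1% — gender 98.6% — diet 0.6%
```

The per-sample models differ mostly along PC1, and nearly all of that
variation lines up with the planted factor (gender), not with the unused
factors — exactly the selection signal the workflow looks for. Running the
downstream analysis (`contextgem.benchmark.recovery_study(0)`) samples
fluxes from each model, tests each reaction for differential activity
between the gender groups and finds the planted subsystem enriched at
BH-adjusted p = 0.0069.

The same study runs end to end from the shell:

```bash
contextgem simulate --seed 0 --out study/
contextgem run study_config.yaml --out results/
```

where the YAML config names the reference model, expression/metadata CSVs,
the thresholding rules, the MEMs to try, and the group comparisons to test;
the output bundle contains one context model per sample, Jaccard/PCA/t-SNE
tables and figures, a configuration-ranking selection report, and
differential/enrichment tables, all listed in a JSON manifest with every
seed recorded.

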