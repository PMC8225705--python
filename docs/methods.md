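# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `contextgem`. Everything stated here is computed by the
package's tests or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Constraint-based core

A metabolic network is the stoichiometric matrix *S* (M metabolites × N
reactions) with flux bounds lb ≤ v ≤ ub per reaction. Under the
steady-state assumption, Σⱼ Sᵢⱼ·vⱼ = 0 for every metabolite i. Flux units
are conventionally mmol·gDW⁻¹·h⁻¹ and are treated as abstract.
Reversibility is encoded purely by the sign of the lower bound.

* **FBA** maximises (or minimises) a linear objective c'v over this
  polytope; it is a linear program solved with HiGHS (scipy). Alternate
  optima are returned as whatever vertex the solver lands on — no
  canonicalisation, because downstream analysis uses sampling, not a
  single FBA solution.
* **FVA** computes per-reaction [min, max] flux, optionally inside the
  region c'v ≥ fraction·optimum.
* **Flux consistency**: reaction j is *blocked* at activity scale ε when
  no feasible distribution gives |vⱼ| ≥ ε. `consistent_subnetwork` is
  implemented as the per-reaction FVA oracle (2N LPs): j is kept iff
  fva_min ≤ −ε or fva_max ≥ +ε. This is the correct-by-construction
  definition; no accelerated variant is enabled.

Tolerances: solver primal feasibility 1e−9, dual 1e−7; every optimal
solution is re-checked for ‖S·v‖∞ ≤ 1e−6 and an error is raised otherwise.
Default ε = 1e−4, chosen relative to the conventional default bound
magnitude of 1000.

## Expression thresholding and GPR mapping

Two thresholding families give the cutoff above which a gene counts as
highly expressed: **per-sample** (a percentile of all genes within one
sample — individuals are biologically distinct, so each sample earns its
own highly-expressed set) and **per-gene** (a percentile, or the mean, of
one gene across samples). Percentiles use linear interpolation between
order statistics (numpy's default convention) everywhere. Ternary calls
use an optional lower cutoff; the default is the mirrored percentile
(100 − p) under the same rule. Ties classify as the more extreme category
(≥ upper → high, ≤ lower → low).

GPR rules (`identifiers` + case-insensitive `and`/`or` + parentheses) are
parsed into expression trees and evaluated over gene values with AND = min
(a complex is limited by its scarcest subunit) and OR = max (isoenzymes
are alternatives). Genes without data are dropped from OR nodes and make
AND nodes evaluate to no-data; a reaction with no rule, or an unevaluable
rule, carries the no-data marker. Evaluating the same tree over ternary
calls with the same min/max algebra gives identical calls whenever the
cutoffs are shared scalars (property-tested).

## Extraction methods

All five return the kept reaction set, the induced submodel (orphan
metabolites and genes pruned), method diagnostics, and the full
configuration. MILPs are solved with HiGHS via `scipy.optimize.milp` at
zero MIP gap, with deterministic variable ordering, so identical inputs
reproduce identical kept sets.

**GIMME.** Stage 1 maximises the required metabolic functionality (RMF),
giving z*. Stage 2 minimises Σⱼ wⱼ·|vⱼ| with wⱼ = max(thresholdⱼ −
exprⱼ, 0) and wⱼ = 0 for reactions without data, subject to steady state,
bounds and c'v ≥ fraction·z* (default fraction 0.9). |v| is linearised by
a positive/negative split. The stage-2 objective is the *inconsistency
score* — flux times expression shortfall. Kept: reactions at or above
threshold plus reactions carrying |v| ≥ ε in the stage-2 optimum. No
default RMF is applied: the objective choice is consequential and must be
explicit.

**iMAT.** Reactions are called −1/0/+1 from ternary expression (no-data =
moderate). The MILP maximises agreements: a +1 reaction agrees when it
carries |v| ≥ ε (forward, or backward if reversible; one binary per
direction, at most one rewarded), a −1 reaction agrees when v = 0.
Indicator logic is encoded as big-M rows on the original flux variables
using the model's own bounds as M (equivalent to an irreversible split,
with fewer variables). Default ε = 1.0 — 1e−3 of the conventional bound
magnitude 1000. Kept: reactions active at the optimum plus moderate /
no-data reactions that remain unblocked in the submodel induced by the
solution; moderate reactions were never penalised, so inactivity at one
MILP vertex is not treated as evidence of absence. The exhaustive
activity-assignment enumeration in `contextgem.validation` reproduces the
MILP objective on every tested fixture.

**FASTCORE.** Given a flux-consistent reference and a core of
known-active reactions, alternates two LPs: one pushes as many unsupported
core reactions as possible to ≥ ε (maximising Σ min(vⱼ, ε)), the next
minimises the L1 norm of flux through non-core reactions while holding the
supported core active; reversible core reactions unsupported forward are
retried with flipped bounds, then one at a time. The support threshold for
including a reaction is |v| > 1e−7. On every tested fixture the output
size equals the brute-force minimal flux-consistent superset, though
minimality is heuristic in general.

**INIT.** Inclusion binaries zⱼ maximise Σⱼ wⱼ·zⱼ (+ Σᵢ wᵐᵢ·uᵢ); zⱼ = 1
forces |vⱼ| ≥ ε via a positive/negative flux split with a direction
binary, zⱼ = 0 forces vⱼ = 0, so every kept reaction carries flux in the
witness distribution. Default weights from expression calls: +1 high, −1
low, 0 moderate/no-data; a log-ratio weighting w = k·log(expr/cutoff) is
available. Strict steady state by default; metabolites given a positive
weight may be net-produced up to b_max (default 1e−2), relaxing S·v = 0 to
S·v = u, u ∈ [0, b_max].

**tINIT.** INIT plus hard task constraints: each task (allowed inputs with
maximum uptake, required outputs with minimum production) gets its own
flux vector confined to the included reactions (lb·z ≤ vᵗ ≤ ub·z) that
must realise the task's net-production pattern. Task-output metabolites
may also be net-produced in the base distribution (without objective
reward): a reaction kept solely to serve a production task could otherwise
never satisfy its own activity constraint. With an empty task list, tINIT
reduces exactly to INIT (tested).

## Model comparison and selection

The presence matrix has one row per reference reaction and one column per
extracted model, entries 1/0. Rows constant across models are removed
(recorded), then each row is centered to mean zero. PCA is the SVD of this
row-centered matrix: models are the observations, reactions the variables;
*only* row centering is applied — no column centering or scaling — so the
component variances decompose the between-model presence variance.

The **variance explained by a factor** on a component is
100·(max |r|)² where the maximum is over all k! assignments of the
factor's k levels to ranks 1..k and r is the Pearson correlation between
the encoded labels and the component scores. Squaring discards the sign,
so level order within an assignment is irrelevant. Enumeration is capped
at k = 8 levels; beyond that a warned Monte-Carlo over orderings is used
(the intended designs have k ≤ 3). The interpretation "orderings of the
levels within a factor" was chosen over "orderings of the factors"; the
alternative reading exists but does not produce a per-factor statistic.

Jaccard index |A∩B| / |A∪B| over kept-reaction sets compares model pairs;
two empty models are defined as identical (index 1, logged). t-SNE (via
scikit-learn, fixed seed, PCA initialisation) validates PCA clusters
visually; its default perplexity floor of 15 reflects where such
embeddings stop being stable, and perplexity must be below the number of
models.

**Selection rule** of the pipeline: rank configurations by the highest
variance-by-factor attained by any experimental factor on PC1 (a method
must capture the *groups defined by the experiment*, not merely variance);
ties break toward the higher PC1 variance fraction.

## ACHR flux sampling

Warmup points are the 2N FVA extreme distributions. Each step picks a
random previously seen point, forms the direction (point − running
center), projects it onto the null space of S, and moves uniformly within
the feasible segment; the center is the running mean of all points seen.
Every 100 steps the state is re-projected onto the null space and drift
beyond ‖S·x‖∞ > 1e−6 aborts with an error. Defaults: burn-in 1000 steps,
thinning 10, 1000 stored samples — the benchmark study uses thinning 2 to
keep 12-model × 10-seed runs fast; thinning is an explicit knob. Every
stored sample is clipped to bounds (within 1e−9) and satisfies the
steady-state residual bound. A single-point region (lb = ub everywhere) is
detected via FVA and returned as constant samples with a flag. Fixed seeds
give bitwise-identical output.

## Differential reactions and subsystem enrichment

For a binary comparison, each reaction's mean sampled flux across models
is correlated with the group indicator (lexicographically second group
encoded 1) by Spearman rank correlation with midranks; two-sided p, raw
p < 0.05 for reaction-level significance, direction from the sign of ρ.
Reactions absent from a model contribute mean flux 0 — in an extracted
model, absence is the strongest form of inactivity. Constant-flux
reactions are flagged and reported non-significant.

Enrichment universe: reactions present in the comparison table that carry
a non-empty subsystem label. Up- and down-regulated sets are tested
separately: p = P[X ≥ k], X ~ Hypergeometric(N, K, n). Benjamini–Hochberg
(step-up, adjᵢ = min over j ≥ i of p₍ⱼ₎·m/j, capped at 1) is applied
across subsystems within one comparison; reaction-level p-values are not
BH-adjusted (both knobs are exposed). Significance is 5% after adjustment.
Multi-level factors are compared pairwise; no omnibus test.

## Synthetic studies

`make_toy_model` builds n pathways (one subsystem each) of m *parallel*
branch reactions from a shared uptake metabolite to a shared secretion
metabolite; all reactions irreversible, uptake bounded at 10, internal
bounds 1000; every internal reaction has a GPR over 1–3 pathway-specific
genes (single gene, two-gene complex, or complex-plus-isoenzyme). Exchange
reactions carry no subsystem label, as in real models — they are
plumbing, and they give the enrichment universe its unlabelled class. The
parallel topology matters: with chained pathways, any core hit drags the
whole chain into a FASTCORE model, so every unaffected pathway forms a
coherent presence block that competes with a planted block on PC1; with
parallel branches, background presence flips are row-independent and only
the planted block is coherent.

`make_expression` draws each gene's baseline once from Normal(2, 0.5) on
the log scale (LogNormal on the raw scale), shifts all genes of an
affected subsystem by the stated log-effect in samples carrying the
stated factor level, and adds i.i.d. Normal(0, noise_sd) per gene and
sample. A truth record lists affected genes, reactions and samples.

The **canonical study** (`make_study`): 6 pathways × 6 branches (38
reactions, ~70 genes), the full 2×2×3 genotype × gender × diet design
(12 samples), one effect of log-size 2.0 (4-fold, knockout-scale) on
`pathway_2` in male samples, noise 0.3. The effect size is deliberately
well inside the detectable regime: a per-sample percentile cutoff *adapts
upward* in effect-carrying samples (the shifted genes occupy much of the
top quantile), which swallows roughly one noise-scale unit of the shift;
at a 2-fold effect recovery is unreliable, at 4-fold the planted block of
6 reactions is recovered nearly deterministically and carries enough
hypergeometric mass (k≈K=6 in a universe of ~15–20) to clear BH across
~6 subsystems at 12 samples. The benchmark fixes study instances 0–9 as
part of its definition and takes the ACHR chain seeds — the stochastic
stage of the analysis — from the caller.

What the generator does *not* emulate: realistic metabolic topology
(loops, cofactors, compartments), microarray/RNA-seq noise structure,
probe-to-gene collapsing, correlated gene effects, or batch effects.
Passing tests demonstrate that the pipeline recovers planted signal under
idealised conditions; they say nothing about sensitivity on real data,
where effect sizes, GPR fidelity and reference-model quality dominate.

## Numerical and degenerate-input choices

* LP/MILP: HiGHS through scipy; MILP integrality tolerance and gap left at
  solver defaults except mip_rel_gap = 0.
* iMAT/INIT big-M values come from the model's own bounds, so bounds must
  be finite for reactions with calls/weights (readers refuse files with
  missing bounds rather than inventing defaults).
* Jaccard of two empty sets = 1 (logged); variance-by-factor of constant
  scores or a single-level factor = 0 with a warning; PCA of an empty
  presence matrix raises.
* Empty GPR → no-data, never 0: GIMME then assigns weight zero, iMAT
  treats the reaction as moderate, INIT as weight 0.
* `extract_submodel` preserves reaction order and all annotations; on an
  empty keep-set it returns a 0×0 model.

## Known limitations

* FASTCORE minimality is heuristic; equality with the brute-force minimum
  is verified on the tested fixture family only.
* The iMAT kept-set rule (active ∪ unblocked-moderate) is one of several
  defensible readings of "the model predicted by the activity vector".
* ACHR convergence is not diagnosed beyond the drift check; mean fluxes
  from 1000 thinned samples are adequate for the toy polytopes here but
  real GEM applications should assess mixing.
* The Spearman construction correlates mean flux with the binary group
  indicator; with two groups this is a rank-sum-style test, and other
  constructions (e.g. correlating against a multi-level ordinal factor)
  would need their own calibration.
* Model I/O covers SBML L3 + FBC v2 (+ Groups) and the community JSON
  schema; MAT-file distributions are out of scope.
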