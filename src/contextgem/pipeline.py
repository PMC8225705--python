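"""Config-driven four-step extraction/analysis pipeline.

The pipeline codifies the guided workflow for analysing omics data with
genome-scale models: (1) load and validate the reference model and reduce
it to its flux-consistent subnetwork; (2) extract one context-specific
model per sample for every (extraction method, thresholding) combination;
(3) compare the extracted model sets — presence matrix, Jaccard, PCA,
variance explained by each experimental factor, optional t-SNE — and rank
the configurations; (4) run flux sampling, differential-reaction detection
and subsystem enrichment on the selected configuration.

Selection rule: the configuration whose PC1 variance is best explained by
any experimental factor wins (a method must capture the groups defined by
the experiment, not just variance); ties break toward the higher PC1
variance fraction.

The output bundle contains CSV tables, SVG figures, a JSON manifest with
every seed and parameter, and a run log, so every artifact is re-derivable
from the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import cbm, compare, enrichment, mems, sampling
from .expression import (ExpressionMatrix, compute_thresholds,
                         gene_activity_calls, map_calls_to_reactions,
                         map_to_reactions, read_expression)
from .io import read_model, write_model
from .model import MetabolicModel, validate_model

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "extract_per_sample", "PipelineError"]


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage; partial outputs are retained."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


# ---------------------------------------------------------------------------
# per-sample extraction for one (MEM, threshold) configuration
# ---------------------------------------------------------------------------

def _reaction_inputs(model: MetabolicModel, expr: ExpressionMatrix,
                     thr_cfg: Mapping, sample: str):
    """Per-reaction continuous values, calls, and threshold for one sample."""
    spec = compute_thresholds(
        expr, rule=thr_cfg.get("rule", "per_sample"),
        statistic=thr_cfg.get("statistic", "percentile"),
        p=float(thr_cfg.get("p", 80.0)),
        lower=thr_cfg.get("lower", "mirror"))
    gene_values = expr.values[sample]
    calls = gene_activity_calls(expr, spec)[sample]
    rxn_calls = map_calls_to_reactions(model, calls)
    if spec.rule == "per_sample":
        upper = float(spec.upper[sample])
        lower = float(spec.lower[sample]) if spec.lower is not None else None
        mapped = map_to_reactions(model, gene_values, upper_cutoff=upper,
                                  lower_cutoff=lower)
        threshold = pd.Series(upper, index=model.reaction_ids)
    else:
        mapped = map_to_reactions(model, gene_values)
        mapped["call"] = rxn_calls
        # per-gene cutoffs mapped through the same min/max algebra
        threshold = map_to_reactions(model, spec.upper)["value"]
    return mapped["value"], rxn_calls, threshold


def extract_per_sample(model: MetabolicModel, expr: ExpressionMatrix,
                       mem_cfg: Mapping, thr_cfg: Mapping,
                       consistent: Optional[set] = None
                       ) -> dict[str, mems.ExtractionResult]:
    """One context model per sample for a (MEM, thresholding) configuration."""
    method = mem_cfg["method"]
    results: dict[str, mems.ExtractionResult] = {}
    for sample in expr.sample_ids:
        values, calls, threshold = _reaction_inputs(model, expr, thr_cfg,
                                                    sample)
        mid = f"{sample}"
        if method == "gimme":
            if "rmf" not in mem_cfg:
                raise ValueError(
                    "GIMME requires an explicit 'rmf' (required metabolic "
                    "functionality); no silent objective default is applied")
            res = mems.gimme(model, values, threshold,
                             rmf=mem_cfg["rmf"],
                             rmf_fraction=float(mem_cfg.get("rmf_fraction", 0.9)),
                             eps=float(mem_cfg.get("eps", cbm.DEFAULT_EPS)),
                             model_id=mid)
        elif method == "imat":
            res = mems.imat(model, calls,
                            eps=float(mem_cfg.get("eps", mems.DEFAULT_IMAT_EPS)),
                            time_limit=mem_cfg.get("time_limit"),
                            model_id=mid)
        elif method == "fastcore":
            core = set(calls.index[calls == 1.0])
            if consistent is not None:
                core &= consistent
            res = mems.fastcore(model, core,
                                eps=float(mem_cfg.get("eps", cbm.DEFAULT_EPS)),
                                model_id=mid)
        elif method in ("init", "tinit"):
            weights = calls.fillna(0.0)
            kwargs = dict(
                production_allowance=float(
                    mem_cfg.get("production_allowance", 1e-2)),
                eps=float(mem_cfg.get("eps", cbm.DEFAULT_EPS)),
                time_limit=mem_cfg.get("time_limit"), model_id=mid)
            if method == "tinit":
                tasks = mem_cfg.get("tasks", [])
                if isinstance(tasks, (str, Path)):
                    tasks = mems.read_tasks(tasks)
                res = mems.tinit(model, weights, tasks=tasks, **kwargs)
            else:
                res = mems.init_extract(model, weights, **kwargs)
        else:
            raise ValueError(f"unknown extraction method {method!r}")
        results[sample] = res
    return results


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _config_name(mem_cfg: Mapping, thr_cfg: Mapping) -> str:
    thr = f"{thr_cfg.get('rule', 'per_sample')}_" \
          f"{thr_cfg.get('statistic', 'percentile')}"
    if thr_cfg.get("statistic", "percentile") == "percentile":
        thr += f"{float(thr_cfg.get('p', 80.0)):g}"
    return f"{mem_cfg['method']}__{thr}"


def run_pipeline(config: Union[str, Path, Mapping],
                 output_dir: Optional[Union[str, Path]] = None) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    ``config`` is a mapping or a path to a YAML file; see the package
    README for the schema.  Artifacts are written under ``output_dir``
    (default: the config's ``output_dir``, default ``contextgem_run``).
    """
    if not isinstance(config, Mapping):
        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    out = Path(output_dir or cfg.get("output_dir", "contextgem_run"))
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s "
                                           "%(name)s: %(message)s"))
    root = logging.getLogger("contextgem")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"config": _jsonable_config(cfg), "seed": seed,
                      "stages": {}}
    try:
        model, consistent = _load_reference(cfg, manifest)
        extractions = _extract_all(cfg, model, consistent, out, manifest)
        selection = _compare_all(cfg, model, extractions, out, manifest, seed)
        _analyse_selected(cfg, model, extractions, selection, out, manifest,
                          seed)
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        root.removeHandler(handler)
        handler.close()
    return manifest


@_stage("load_reference")
def _load_reference(cfg, manifest):
    model = read_model(cfg["reference_model"])
    issues = validate_model(model)
    if issues:
        raise ValueError("invalid reference model: " + "; ".join(issues))
    eps = float(cfg.get("consistency_eps", cbm.DEFAULT_EPS))
    consistent = cbm.consistent_subnetwork(model, eps=eps)
    n_blocked = model.n_reactions - len(consistent)
    logger.info("reference %s: %d reactions, %d blocked at eps=%g",
                model.model_id, model.n_reactions, n_blocked, eps)
    manifest["stages"]["load_reference"] = {
        "model_id": model.model_id, "n_reactions": model.n_reactions,
        "n_metabolites": model.n_metabolites,
        "n_blocked": n_blocked, "consistency_eps": eps}
    from .model import extract_submodel
    work = extract_submodel(model, consistent, model_id=model.model_id)
    return work, consistent


@_stage("extraction")
def _extract_all(cfg, model, consistent, out, manifest):
    expr = read_expression(cfg["expression"], cfg.get("metadata"))
    extractions = {}
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    for mem_cfg in cfg["mems"]:
        for thr_cfg in cfg.get("thresholds", [{}]):
            name = _config_name(mem_cfg, thr_cfg)
            per_sample = extract_per_sample(model, expr, mem_cfg, thr_cfg,
                                            consistent=consistent)
            extractions[name] = (per_sample, expr)
            record = {}
            for sample, res in per_sample.items():
                path = models_dir / f"{name}__{sample}.json"
                write_model(res.context_model, path, format="json")
                (models_dir / f"{name}__{sample}.result.json").write_text(
                    json.dumps({"kept_reactions": sorted(res.kept_reactions),
                                "diagnostics": _jsonable_config(
                                    {k: v for k, v in res.diagnostics.items()
                                     if not isinstance(v, pd.Series)}),
                                "config": res.config}, indent=1))
                record[sample] = {"size": res.size, "file": path.name}
            manifest["stages"].setdefault("extraction", {})[name] = record
            logger.info("extracted %s: sizes %s", name,
                        {s: r.size for s, r in per_sample.items()})
    return extractions


@_stage("comparison")
def _compare_all(cfg, model, extractions, out, manifest, seed):
    cmp_dir = out / "comparison"
    cmp_dir.mkdir(exist_ok=True)
    report_rows = []
    details = {}
    for name, (per_sample, expr) in extractions.items():
        sets = {s: r.kept_reactions for s, r in per_sample.items()}
        jac = compare.jaccard_matrix(sets)
        jac.to_csv(cmp_dir / f"{name}__jaccard.csv")
        try:
            pm = compare.presence_matrix(sets, model,
                                         model_factors=expr.factors)
            scores, fractions = compare.pca_reactions(pm)
        except ValueError as exc:
            logger.warning("comparison for %s skipped: %s", name, exc)
            report_rows.append((name, np.nan, np.nan, ""))
            continue
        scores.to_csv(cmp_dir / f"{name}__pca_scores.csv")
        pm.matrix.to_csv(cmp_dir / f"{name}__presence_centered.csv")
        factor_var = {}
        for factor in expr.factors.columns:
            factor_var[factor] = compare.variance_by_factor(
                scores["PC1"], expr.factors[factor])
        best_factor = max(factor_var, key=factor_var.get) if factor_var else ""
        perplexity = float(cfg.get("tsne", {}).get("perplexity", 15.0))
        if perplexity < len(scores):
            emb = compare.tsne_embed(pm, perplexity=perplexity, seed=seed)
            emb.to_csv(cmp_dir / f"{name}__tsne.csv")
        else:
            logger.info("t-SNE skipped for %s: perplexity %g ≥ %d models",
                        name, perplexity, len(scores))
        _plot_scores(scores, expr.factors, fractions,
                     cmp_dir / f"{name}__pca.svg")
        details[name] = {"pc1_variance_fraction": float(fractions[0]),
                         "variance_by_factor_pc1": factor_var,
                         "best_factor": best_factor}
        report_rows.append((name, float(fractions[0]),
                            factor_var.get(best_factor, np.nan), best_factor))
    report = pd.DataFrame(report_rows, columns=[
        "configuration", "pc1_variance_fraction",
        "best_factor_variance_pct", "best_factor"])
    # primary criterion: variance explained by an experimental factor on PC1;
    # tie-break: PC1 variance fraction
    report = report.sort_values(
        ["best_factor_variance_pct", "pc1_variance_fraction"],
        ascending=False).reset_index(drop=True)
    report.to_csv(cmp_dir / "selection_report.csv", index=False)
    selected = report.iloc[0]["configuration"] if len(report) else None
    manifest["stages"]["comparison"] = {"details": details,
                                        "selected": selected}
    logger.info("selected configuration: %s", selected)
    return selected


@_stage("analysis")
def _analyse_selected(cfg, model, extractions, selection, out, manifest,
                      seed):
    if selection is None or selection not in extractions:
        raise ValueError("no configuration selected for analysis")
    per_sample, expr = extractions[selection]
    ana_dir = out / "analysis"
    ana_dir.mkdir(exist_ok=True)
    smp_cfg = cfg.get("sampling", {})
    n_samples = int(smp_cfg.get("n_samples", 1000))
    burn_in = int(smp_cfg.get("burn_in", 1000))
    thinning = int(smp_cfg.get("thinning", 10))
    means = {}
    for i, (sample, res) in enumerate(per_sample.items()):
        if res.context_model.n_reactions == 0:
            means[sample] = pd.Series(dtype=float)
            continue
        fs = sampling.achr_sample(res.context_model, n_samples=n_samples,
                                  seed=seed + i, burn_in=burn_in,
                                  thinning=thinning)
        means[sample] = sampling.mean_fluxes(fs)
    mean_table = pd.DataFrame(means).T.fillna(0.0)
    mean_table.to_csv(ana_dir / "mean_fluxes.csv")
    manifest["stages"]["analysis"] = {
        "selected": selection,
        "sampling": {"n_samples": n_samples, "burn_in": burn_in,
                     "thinning": thinning, "base_seed": seed},
        "comparisons": []}
    alpha = float(cfg.get("alpha", 0.05))
    submap = model.subsystem_map()
    for comparison in cfg.get("comparisons", []):
        factor = comparison["factor"]
        a, b = comparison["group_a"], comparison["group_b"]
        labels = expr.factors[factor]
        members = labels[labels.isin([a, b])]
        if members.nunique() != 2:
            logger.warning("comparison %s: %s vs %s has <2 groups, skipped",
                           factor, a, b)
            continue
        diff = enrichment.differential_reactions(
            mean_table.loc[members.index], members, alpha=alpha)
        tag = f"{factor}_{a}_vs_{b}"
        diff.to_csv(ana_dir / f"differential__{tag}.csv")
        tables = []
        for direction in ("up", "down"):
            enr = enrichment.subsystem_enrichment(diff, submap,
                                                  direction=direction,
                                                  alpha=alpha)
            tables.append(enr.reset_index())
        enr_all = pd.concat(tables, ignore_index=True)
        enr_all.to_csv(ana_dir / f"enrichment__{tag}.csv", index=False)
        manifest["stages"]["analysis"]["comparisons"].append({
            "factor": factor, "group_a": a, "group_b": b,
            "n_significant": int((diff["direction"] != "ns").sum()),
            "files": [f"differential__{tag}.csv", f"enrichment__{tag}.csv"],
        })


def _plot_scores(scores: pd.DataFrame, factors: pd.DataFrame,
                 fractions: np.ndarray, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    n_f = max(1, len(factors.columns))
    fig, axes = plt.subplots(1, n_f, figsize=(4.2 * n_f, 3.6), squeeze=False)
    y = scores["PC2"] if "PC2" in scores else scores["PC1"] * 0.0
    for ax, factor in zip(axes[0], list(factors.columns) or [None]):
        if factor is None:
            ax.scatter(scores["PC1"], y)
        else:
            for level in sorted(factors[factor].unique()):
                mask = (factors.loc[scores.index, factor] == level)
                ax.scatter(scores.loc[mask.to_numpy(), "PC1"],
                           y[mask.to_numpy()], label=str(level), s=30)
            ax.legend(title=factor, fontsize=8)
        ax.set_xlabel(f"PC1 ({100 * fractions[0]:.1f}%)")
        if len(fractions) > 1:
            ax.set_ylabel(f"PC2 ({100 * fractions[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _jsonable_config(cfg):
    def conv(x):
        if isinstance(x, Mapping):
            return {str(k): conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple, set)):
            return [conv(v) for v in x]
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, Path):
            return str(x)
        if isinstance(x, (str, int, float, bool)) or x is None:
            return x
        return str(x)
    return conv(cfg)
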