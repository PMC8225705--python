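"""Expression ingestion, thresholding, and GPR mapping to reactions.

Two thresholding families are supported, mirroring how activity cutoffs are
usually chosen when integrating transcriptomics with a metabolic network:

* ``per_sample`` — a percentile of all gene values within each sample
  (every sample gets its own cutoff; biologically distinct individuals get
  distinct highly-expressed gene sets);
* ``per_gene`` — a percentile, or the mean, of each gene's values across
  samples (every gene gets its own cutoff shared by all samples).

Percentiles use linear interpolation between order statistics (the
"inclusive" convention, numpy's default) everywhere.  Ties at a cutoff
classify as the more extreme category: value ≥ upper cutoff → highly
expressed (+1), value ≤ lower cutoff → lowly expressed (−1).

Gene-level values or ternary calls are mapped to reactions through GPR
rules with AND = min and OR = max.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import MetabolicModel

__all__ = ["ExpressionMatrix", "ThresholdSpec", "read_expression",
           "compute_thresholds", "gene_activity_calls", "map_to_reactions",
           "map_calls_to_reactions"]


@dataclass
class ExpressionMatrix:
    """Normalized gene × sample expression with per-sample factor labels.

    ``values``: DataFrame, rows = genes, columns = samples (NaN = missing).
    ``factors``: DataFrame, rows = samples, one column per experimental
    factor (e.g. diet / gender / genotype), all categorical strings.
    """

    values: pd.DataFrame
    factors: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene id(s): {list(dup)}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample id(s): {list(dup)}")
        if len(self.factors):
            missing = set(self.values.columns) - set(self.factors.index)
            if missing:
                raise ValueError(
                    f"sample(s) without metadata: {sorted(missing)}")
            self.factors = self.factors.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_expression(path: Union[str, Path],
                    metadata_path: Optional[Union[str, Path]] = None
                    ) -> ExpressionMatrix:
    """Read a gene × sample CSV/TSV (first column gene id, header = samples)
    plus an optional sample-metadata CSV (first column sample id, one column
    per factor)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    values = pd.read_csv(path, sep=sep, index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    factors = pd.DataFrame(index=pd.Index(values.columns))
    if metadata_path is not None:
        factors = pd.read_csv(metadata_path, index_col=0)
        factors.index = factors.index.astype(str)
    return ExpressionMatrix(values=values.astype(float), factors=factors)


@dataclass
class ThresholdSpec:
    """Activity cutoffs for calling genes highly / lowly expressed.

    ``rule``: "per_sample" or "per_gene" — whether cutoffs are indexed by
    sample or by gene.  ``upper`` holds the highly-expressed cutoff;
    ``lower`` (optional) the lowly-expressed cutoff for the ternary split.
    """

    rule: str
    statistic: str
    upper: pd.Series
    lower: Optional[pd.Series] = None

    def __post_init__(self):
        if self.rule not in ("per_sample", "per_gene"):
            raise ValueError(f"unknown thresholding rule {self.rule!r}")
        if self.lower is not None:
            both = pd.concat({"lo": self.lower, "hi": self.upper}, axis=1).dropna()
            bad = both.index[both["lo"] > both["hi"]]
            if len(bad):
                raise ValueError(
                    f"lower cutoff exceeds upper cutoff for {list(bad)}")


def compute_thresholds(expr: ExpressionMatrix, rule: str = "per_sample",
                       statistic: str = "percentile", p: float = 80.0,
                       lower: Union[str, float, None] = None) -> ThresholdSpec:
    """Compute activity cutoffs.

    ``statistic`` is "percentile" (with ``p`` ∈ [0, 100]) or "mean"
    (per_gene only: the gene's mean across samples as its cutoff).
    ``lower`` controls the lowly-expressed cutoff: None (no ternary split),
    "mirror" (the (100 − p)th percentile under the same rule), or an
    explicit percentile value.
    """
    if rule not in ("per_sample", "per_gene"):
        raise ValueError(f"unknown thresholding rule {rule!r}")
    if statistic not in ("percentile", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "percentile" and not 0.0 <= p <= 100.0:
        raise ValueError("percentile must lie in [0, 100]")
    axis = 0 if rule == "per_sample" else 1  # reduce over genes | samples
    counts = expr.values.notna().sum(axis=axis)
    if (counts == 0).any():
        empty = list(counts.index[counts == 0])
        kind = "sample" if rule == "per_sample" else "gene"
        raise ValueError(f"all values missing for {kind}(s) {empty}")
    if (counts < 2).any():
        few = list(counts.index[counts < 2])
        kind = "sample" if rule == "per_sample" else "gene"
        raise ValueError(f"fewer than 2 finite values for {kind}(s) {few}")

    def _stat(q: float) -> pd.Series:
        return expr.values.quantile(q / 100.0, axis=axis,
                                    interpolation="linear")

    if statistic == "mean":
        if rule != "per_gene":
            raise ValueError("statistic 'mean' is defined per gene")
        upper = expr.values.mean(axis=1)
    else:
        upper = _stat(p)
    lower_series = None
    if lower is not None:
        if statistic == "mean":
            raise ValueError("lower cutoff undefined for statistic 'mean'")
        lower_p = (100.0 - p) if lower == "mirror" else float(lower)
        lower_series = _stat(min(lower_p, p))
    return ThresholdSpec(rule=rule, statistic=statistic, upper=upper,
                         lower=lower_series)


def _broadcast(spec_series: pd.Series, spec: ThresholdSpec,
               values: pd.DataFrame) -> pd.DataFrame:
    if spec.rule == "per_sample":
        return pd.DataFrame(
            np.broadcast_to(spec_series[values.columns].to_numpy()[None, :],
                            values.shape),
            index=values.index, columns=values.columns)
    return pd.DataFrame(
        np.broadcast_to(spec_series[values.index].to_numpy()[:, None],
                        values.shape),
        index=values.index, columns=values.columns)


def gene_activity_calls(expr: ExpressionMatrix,
                        spec: ThresholdSpec) -> pd.DataFrame:
    """Ternary gene × sample calls: +1 high, −1 low, 0 moderate, NaN no data.

    +1 iff value ≥ upper cutoff; −1 iff value ≤ lower cutoff (when a lower
    cutoff exists); 0 otherwise.
    """
    values = expr.values
    key = values.columns if spec.rule == "per_sample" else values.index
    missing = set(key) - set(spec.upper.index)
    if missing:
        raise ValueError(f"thresholds missing for {sorted(missing)}")
    upper = _broadcast(spec.upper, spec, values)
    calls = pd.DataFrame(0.0, index=values.index, columns=values.columns)
    calls = calls.mask(values >= upper, 1.0)
    if spec.lower is not None:
        lower = _broadcast(spec.lower, spec, values)
        calls = calls.mask(values <= lower, -1.0)
    calls = calls.mask(values.isna(), np.nan)
    return calls


def _evaluate_gprs(model: MetabolicModel, per_gene: pd.Series) -> pd.Series:
    table = {g: (None if pd.isna(v) else float(v))
             for g, v in per_gene.items()}
    out = []
    for j in range(model.n_reactions):
        g = model.gpr_rules[j]
        if g is None:
            out.append(np.nan)
        else:
            v = g.value(table)
            out.append(np.nan if v is None else v)
    return pd.Series(out, index=model.reaction_ids, dtype=float)


def map_to_reactions(model: MetabolicModel, gene_values: pd.Series,
                     upper_cutoff: Optional[float] = None,
                     lower_cutoff: Optional[float] = None) -> pd.DataFrame:
    """Map per-gene continuous values to reactions through the GPR rules.

    AND nodes take the minimum of their children, OR nodes the maximum;
    genes missing from ``gene_values`` are dropped from OR nodes and make
    AND nodes evaluate to no-data (NaN).  An empty GPR yields no-data.

    Returns a DataFrame indexed by reaction id with columns ``value`` and
    ``call`` (+1 / 0 / −1 / NaN); the call is derived by thresholding the
    mapped value against the scalar cutoffs (all-zero when no cutoff is
    given).
    """
    value = _evaluate_gprs(model, gene_values)
    call = pd.Series(0.0, index=value.index)
    if upper_cutoff is not None:
        call = call.mask(value >= upper_cutoff, 1.0)
    if lower_cutoff is not None:
        call = call.mask(value <= lower_cutoff, -1.0)
    call = call.mask(value.isna(), np.nan)
    return pd.DataFrame({"value": value, "call": call})


def map_calls_to_reactions(model: MetabolicModel,
                           gene_calls: pd.Series) -> pd.Series:
    """Map ternary per-gene calls to per-reaction calls with the same
    min/max algebra.  Agrees with thresholding the mapped continuous value
    whenever gene calls and cutoffs are shared."""
    return _evaluate_gprs(model, gene_calls)
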