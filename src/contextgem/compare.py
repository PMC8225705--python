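"""Model comparison and MEM-selection statistics.

Extracted models are compared through their reaction content: a binary
presence matrix (reaction × model) from which constant rows are removed and
whose rows are zero-centered, pairwise Jaccard indices, PCA on reactions
(models are the observations, reactions the variables; only row centering is
applied — no column centering or scaling), the percentage of a component's
variance attributable to an experimental factor, and a t-SNE embedding for
visual confirmation of the PCA clusters.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .mems import ExtractionResult
from .model import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = ["PresenceMatrix", "presence_matrix", "jaccard_matrix",
           "pca_reactions", "variance_by_factor", "tsne_embed"]

#: beyond this many factor levels the k! ordering enumeration is replaced by
#: Monte-Carlo over orderings (with a warning)
MAX_ENUMERATED_LEVELS = 8


@dataclass
class PresenceMatrix:
    """Reaction × model presence matrix after filtering and centering.

    ``matrix`` holds the zero-centered rows (real-valued); ``raw`` the
    retained binary rows; ``filtered_reactions`` the reactions removed for
    being present or absent in every model.  ``model_factors`` carries the
    factor labels inherited from each model's source sample.
    """

    matrix: pd.DataFrame
    raw: pd.DataFrame
    filtered_reactions: list[str]
    model_factors: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def model_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.matrix.index)


def _kept_sets(models: Union[Sequence[ExtractionResult],
                             Mapping[str, set]]) -> dict[str, set]:
    if isinstance(models, Mapping):
        return {str(k): set(v) for k, v in models.items()}
    out = {}
    for i, res in enumerate(models):
        mid = res.context_model.model_id or f"model_{i}"
        if mid in out:
            mid = f"{mid}_{i}"
        out[mid] = set(res.kept_reactions)
    return out


def presence_matrix(models: Union[Sequence[ExtractionResult], Mapping[str, set]],
                    reference: MetabolicModel,
                    model_factors: Optional[pd.DataFrame] = None
                    ) -> PresenceMatrix:
    """Build the filtered, row-centered presence matrix.

    Rows are the reference reactions that vary across models (present in
    some, absent in others); reactions present or absent in all models are
    recorded in ``filtered_reactions``.  Row means are centered to zero.
    """
    sets = _kept_sets(models)
    if len(sets) < 2:
        raise ValueError("presence matrix requires at least 2 models")
    ref_rxns = set(reference.reaction_ids)
    for mid, kept in sets.items():
        stray = kept - ref_rxns
        if stray:
            raise ValueError(
                f"model {mid!r} contains reaction(s) not in the reference "
                f"model: {sorted(stray)[:5]} — mismatched references?")
    raw = pd.DataFrame(
        {mid: [1.0 if r in kept else 0.0 for r in reference.reaction_ids]
         for mid, kept in sets.items()},
        index=list(reference.reaction_ids))
    row_sums = raw.sum(axis=1)
    constant = (row_sums == 0) | (row_sums == len(sets))
    filtered = list(raw.index[constant])
    raw = raw.loc[~constant]
    centered = raw.sub(raw.mean(axis=1), axis=0)
    factors = (model_factors.loc[list(sets)] if model_factors is not None
               else pd.DataFrame(index=list(sets)))
    return PresenceMatrix(matrix=centered, raw=raw,
                          filtered_reactions=filtered, model_factors=factors)


def jaccard_matrix(models: Union[Sequence[ExtractionResult],
                                 Mapping[str, set]],
                   distance: bool = False) -> pd.DataFrame:
    """Pairwise Jaccard index |A∩B|/|A∪B| over kept-reaction sets.

    Two empty sets are defined as identical (index 1), logged.  With
    ``distance=True`` returns 1 − index.
    """
    sets = _kept_sets(models)
    if len(sets) < 2:
        raise ValueError("jaccard matrix requires at least 2 models")
    ids = list(sets)
    out = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        union = sets[a] | sets[b]
        if not union:
            logger.info("jaccard(%s, %s): both reaction sets empty, "
                        "index defined as 1", a, b)
            idx = 1.0
        else:
            idx = len(sets[a] & sets[b]) / len(union)
        out.loc[a, b] = out.loc[b, a] = idx
    return 1.0 - out if distance else out


def pca_reactions(pm: PresenceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the row-centered presence matrix via SVD.

    Returns (scores, variance_fractions): scores is a model × component
    DataFrame of coordinates, variance_fractions sums to 1 over all
    components.
    """
    if pm.matrix.empty:
        raise ValueError("presence matrix is empty (no varying reactions)")
    X = pm.matrix.to_numpy()  # reactions × models, rows centered
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    total = var.sum()
    fractions = var / total if total > 0 else var
    scores = (Vt.T * s)  # model coordinates on each component
    k = len(s)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=pm.model_ids, columns=cols), fractions


def variance_by_factor(scores: Union[pd.Series, np.ndarray],
                       factor: Union[pd.Series, Sequence[str]],
                       rng: Optional[np.random.Generator] = None,
                       n_montecarlo: int = 5000) -> float:
    """Percentage of a component's variance explained by a factor.

    For each of the k! assignments of the factor's k levels to numeric
    ranks 1..k, the Pearson correlation between the encoded labels and the
    component scores is computed; the result is 100·(max |r|)².  The square
    discards the sign, so the level order within an assignment never
    matters.  Beyond 8 levels the enumeration switches to Monte-Carlo over
    orderings (with a warning).  Constant scores or a constant factor make
    the correlation undefined; 0 is returned with a warning.
    """
    y = np.asarray(pd.Series(scores), dtype=float)
    labels = pd.Series(factor).astype(str).to_numpy()
    if len(y) != len(labels):
        raise ValueError("scores and factor labels differ in length")
    levels = sorted(set(labels))
    k = len(levels)
    if k < 2 or np.ptp(y) == 0.0:
        warnings.warn("variance_by_factor undefined for constant scores or "
                      "a single-level factor; returning 0", stacklevel=2)
        return 0.0
    y_c = y - y.mean()
    y_norm = math.sqrt((y_c ** 2).sum())
    level_idx = np.array([levels.index(l) for l in labels])

    def r_for(order: Sequence[int]) -> float:
        enc = np.asarray(order, dtype=float)[level_idx]
        e_c = enc - enc.mean()
        denom = math.sqrt((e_c ** 2).sum()) * y_norm
        if denom == 0.0:
            return 0.0
        return abs(float(e_c @ y_c) / denom)

    if k <= MAX_ENUMERATED_LEVELS:
        orders = itertools.permutations(range(1, k + 1))
    else:
        warnings.warn(f"{k} factor levels: enumerating {k}! orderings is "
                      f"infeasible, sampling {n_montecarlo} random orderings",
                      stacklevel=2)
        rng = rng or np.random.default_rng(0)
        orders = (rng.permutation(k) + 1 for _ in range(n_montecarlo))
    best = max(r_for(o) for o in orders)
    return 100.0 * best ** 2


def tsne_embed(pm: PresenceMatrix, perplexity: float = 15.0,
               seed: int = 0) -> pd.DataFrame:
    """2-D t-SNE embedding of the models (deterministic for a fixed seed).

    Requires perplexity < number of models; the default of 15 reflects the
    floor below which t-SNE clusterings of presence matrices stop being
    stable.
    """
    n = len(pm.model_ids)
    if perplexity >= n:
        raise ValueError(
            f"perplexity ({perplexity}) must be smaller than the number of "
            f"models ({n})")
    from sklearn.manifold import TSNE
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca").fit_transform(pm.matrix.to_numpy().T)
    return pd.DataFrame(emb, index=pm.model_ids, columns=["tsne1", "tsne2"])
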