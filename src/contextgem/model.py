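"""Constraint-based metabolic network container.

A genome-scale metabolic model (GEM) is held as a stoichiometric matrix S
(metabolites × reactions) with per-reaction flux bounds, objective
coefficients, GPR rules and subsystem labels.  Flux units are conventionally
mmol·gDW⁻¹·h⁻¹ but are treated as abstract throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .gpr import GPR, parse_gpr

__all__ = ["MetabolicModel", "FluxResult", "extract_submodel", "validate_model",
           "ModelValidationError"]


class ModelValidationError(ValueError):
    """Raised when a model violates its structural invariants."""


@dataclass
class MetabolicModel:
    """Stoichiometric network with bounds, objective, GPRs and subsystems.

    Reversibility is encoded purely by the sign of the lower bound
    (lower_bound < 0 means the reaction may run backwards); no separate flag
    is stored.
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: sp.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective_coeffs: np.ndarray
    gpr_rules: list[Optional[GPR]]
    subsystems: list[str]
    gene_ids: list[str]
    model_id: str = "model"

    def __post_init__(self):
        self.S = sp.csc_matrix(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.objective_coeffs = np.asarray(self.objective_coeffs, dtype=float)

    # -- shape ---------------------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def reversibility(self) -> np.ndarray:
        """Boolean per reaction: may the reaction carry negative flux."""
        return self.lower_bounds < 0

    def reaction_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except AttributeError:
            self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
            return self._rxn_index[rid]

    def gpr_string(self, j: int) -> str:
        g = self.gpr_rules[j]
        return "" if g is None else g.to_string()

    def subsystem_map(self) -> dict[str, str]:
        return dict(zip(self.reaction_ids, self.subsystems))

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            objective_coeffs=self.objective_coeffs.copy(),
            gpr_rules=list(self.gpr_rules),
            subsystems=list(self.subsystems),
            gene_ids=list(self.gene_ids),
            model_id=self.model_id,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.reaction_ids == other.reaction_ids
            and self.metabolite_ids == other.metabolite_ids
            and self.gene_ids == other.gene_ids
            and self.subsystems == other.subsystems
            and self.gpr_rules == other.gpr_rules
            and np.array_equal(self.lower_bounds, other.lower_bounds)
            and np.array_equal(self.upper_bounds, other.upper_bounds)
            and np.array_equal(self.objective_coeffs, other.objective_coeffs)
            and (self.S != other.S).nnz == 0
        )

    def __repr__(self):
        return (f"MetabolicModel({self.model_id!r}: {self.n_reactions} reactions, "
                f"{self.n_metabolites} metabolites, {len(self.gene_ids)} genes)")


@dataclass
class FluxResult:
    """Outcome of a flux optimisation.

    ``fluxes`` is indexed like the model's reactions and is None unless
    ``status == "optimal"``.
    """

    status: str                      # optimal | infeasible | unbounded
    objective_value: Optional[float] = None
    fluxes: Optional[np.ndarray] = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def build_model(
    reactions: Sequence[tuple[str, Mapping[str, float], float, float]],
    gprs: Optional[Mapping[str, str]] = None,
    subsystems: Optional[Mapping[str, str]] = None,
    objective: Optional[Mapping[str, float]] = None,
    model_id: str = "model",
) -> MetabolicModel:
    """Assemble a model from (reaction id, {metabolite: coeff}, lb, ub) tuples.

    Convenience constructor used by tests and the synthetic generator;
    metabolite order follows first appearance, gene order follows GPR order.
    """
    gprs = gprs or {}
    subsystems = subsystems or {}
    objective = objective or {}
    rxn_ids = [r[0] for r in reactions]
    met_ids: list[str] = []
    met_index: dict[str, int] = {}
    rows, cols, vals = [], [], []
    for j, (rid, stoich, lb, ub) in enumerate(reactions):
        for mid, coeff in stoich.items():
            if mid not in met_index:
                met_index[mid] = len(met_ids)
                met_ids.append(mid)
            rows.append(met_index[mid])
            cols.append(j)
            vals.append(float(coeff))
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    lower = np.array([r[2] for r in reactions], dtype=float)
    upper = np.array([r[3] for r in reactions], dtype=float)
    gpr_list = [parse_gpr(gprs.get(rid, "")) for rid in rxn_ids]
    genes: list[str] = []
    seen: set[str] = set()
    for g in gpr_list:
        if g is not None:
            for name in sorted(g.genes()):
                if name not in seen:
                    seen.add(name)
                    genes.append(name)
    obj = np.array([float(objective.get(rid, 0.0)) for rid in rxn_ids])
    subs = [subsystems.get(rid, "") for rid in rxn_ids]
    return MetabolicModel(rxn_ids, met_ids, S, lower, upper, obj,
                          gpr_list, subs, genes, model_id=model_id)


def validate_model(model: MetabolicModel) -> list[str]:
    """Return every structural invariant violation; empty list iff valid."""
    issues: list[str] = []
    M, N = model.S.shape
    if M != model.n_metabolites:
        issues.append(
            f"S has {M} rows but model lists {model.n_metabolites} metabolites")
    if N != model.n_reactions:
        issues.append(
            f"S has {N} columns but model lists {model.n_reactions} reactions")
    for name, ids in (("reaction", model.reaction_ids),
                      ("metabolite", model.metabolite_ids),
                      ("gene", model.gene_ids)):
        dupes = {x for x in ids if ids.count(x) > 1} if len(ids) != len(set(ids)) else set()
        for d in sorted(dupes):
            issues.append(f"duplicate {name} id {d!r}")
    n = min(N, model.n_reactions, len(model.lower_bounds), len(model.upper_bounds))
    for arr, label in ((model.lower_bounds, "lower_bounds"),
                       (model.upper_bounds, "upper_bounds"),
                       (model.objective_coeffs, "objective_coeffs")):
        if len(arr) != model.n_reactions:
            issues.append(f"{label} has length {len(arr)}, expected {model.n_reactions}")
    for j in range(n):
        if model.lower_bounds[j] > model.upper_bounds[j]:
            issues.append(
                f"reaction {model.reaction_ids[j]!r}: lower bound "
                f"{model.lower_bounds[j]} exceeds upper bound {model.upper_bounds[j]}")
    known = set(model.gene_ids)
    for j, g in enumerate(model.gpr_rules):
        if g is None:
            continue
        for gene in sorted(g.genes() - known):
            issues.append(
                f"reaction {model.reaction_ids[j]!r}: GPR references gene "
                f"{gene!r} absent from gene_ids")
    return issues


def extract_submodel(model: MetabolicModel, keep_reactions: Iterable[str],
                     model_id: Optional[str] = None) -> MetabolicModel:
    """Submodel with exactly ``keep_reactions``; orphan metabolites and genes pruned.

    Bounds, objective coefficients, GPRs and subsystem labels are carried
    over unchanged.  Reaction order follows the parent model.
    """
    keep = set(keep_reactions)
    unknown = keep - set(model.reaction_ids)
    if unknown:
        raise KeyError(
            f"unknown reaction id(s) not in model: {sorted(unknown)}")
    cols = [j for j, rid in enumerate(model.reaction_ids) if rid in keep]
    S_sub = model.S[:, cols] if cols else sp.csc_matrix((0, 0))
    if cols:
        used_rows = np.flatnonzero(np.abs(S_sub).sum(axis=1).A1 > 0)
        S_sub = S_sub[used_rows, :]
        met_ids = [model.metabolite_ids[i] for i in used_rows]
    else:
        met_ids = []
    gprs = [model.gpr_rules[j] for j in cols]
    genes: list[str] = []
    referenced: set[str] = set()
    for g in gprs:
        if g is not None:
            referenced |= g.genes()
    genes = [g for g in model.gene_ids if g in referenced]
    return MetabolicModel(
        reaction_ids=[model.reaction_ids[j] for j in cols],
        metabolite_ids=met_ids,
        S=sp.csc_matrix(S_sub),
        lower_bounds=model.lower_bounds[cols] if cols else np.empty(0),
        upper_bounds=model.upper_bounds[cols] if cols else np.empty(0),
        objective_coeffs=model.objective_coeffs[cols] if cols else np.empty(0),
        gpr_rules=gprs,
        subsystems=[model.subsystems[j] for j in cols],
        gene_ids=genes,
        model_id=model_id or f"{model.model_id}_sub",
    )
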