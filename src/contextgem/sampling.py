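"""Artificial-centering hit-and-run (ACHR) flux sampling.

ACHR draws approximately uniform samples from the steady-state flux
polytope {v : S·v = 0, lb ≤ v ≤ ub}.  Directions are generated as
(random previously seen point − running center), projected onto the null
space of S, which concentrates proposals along the polytope's long axes.
Warmup points are the FVA extreme solutions (2 per reaction by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from . import cbm
from .model import MetabolicModel

__all__ = ["FluxSamples", "achr_sample", "mean_fluxes"]

_DIR_TOL = 1e-9
_DRIFT_TOL = 1e-6
_REPROJECT_EVERY = 100


@dataclass
class FluxSamples:
    """Sampled flux distributions for one model.

    ``samples``: DataFrame, rows = samples, columns = reaction ids.  Every
    stored sample satisfies ‖S·v‖∞ ≤ 1e−6 and the bounds within 1e−9.
    ``degenerate`` flags a single-point feasible region.
    """

    samples: pd.DataFrame
    model_id: str
    seed: int
    n_samples: int
    burn_in: int
    thinning: int
    n_warmup: int
    degenerate: bool = False

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)

    def metadata(self) -> dict:
        return {"model_id": self.model_id, "seed": self.seed,
                "n_samples": self.n_samples, "burn_in": self.burn_in,
                "thinning": self.thinning, "n_warmup": self.n_warmup,
                "degenerate": self.degenerate}


def achr_sample(model: MetabolicModel, n_samples: int = 1000, seed: int = 0,
                n_warmup: Optional[int] = None, burn_in: int = 1000,
                thinning: int = 10) -> FluxSamples:
    """Sample ``n_samples`` flux distributions with ACHR.

    Warmup points are the per-reaction FVA minimisers/maximisers.  Chain:
    center = running mean of all points seen; direction = (random previous
    point − center) projected onto null(S); the step is uniform within the
    feasible segment.  Every ``thinning``-th post-burn-in point is stored.
    A fixed seed yields bitwise-identical output.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be ≥ 1")
    n = model.n_reactions
    if n == 0:
        raise ValueError("cannot sample an empty model")
    rng = np.random.default_rng(seed)

    ranges = cbm.fva(model, objective_fraction=0.0)  # errors if infeasible
    lb, ub = model.lower_bounds, model.upper_bounds
    span = (ranges["maximum"] - ranges["minimum"]).to_numpy()
    degenerate = bool(np.all(span < 1e-9))

    # warmup: FVA extreme flux distributions (2 per reaction)
    warmup_pts = []
    for rid in model.reaction_ids:
        j = model.reaction_index(rid)
        c = np.zeros(n)
        c[j] = 1.0
        for direction in ("min", "max"):
            r = cbm.fba(model, objective=c, direction=direction)
            warmup_pts.append(r.fluxes)
    points = np.array(warmup_pts)
    if n_warmup is not None:
        if n_warmup < 2:
            raise ValueError("n_warmup must be ≥ 2")
        order = rng.permutation(len(points))[:n_warmup]
        points = points[order]

    if degenerate:
        x = points.mean(axis=0)
        samples = np.tile(x, (n_samples, 1))
        return FluxSamples(
            samples=pd.DataFrame(samples, columns=list(model.reaction_ids)),
            model_id=model.model_id, seed=seed, n_samples=n_samples,
            burn_in=burn_in, thinning=thinning, n_warmup=len(points),
            degenerate=True)

    N = null_space(model.S.toarray()) if model.n_metabolites else np.eye(n)
    S_dense = model.S.toarray() if model.n_metabolites else None

    def project(vec: np.ndarray) -> np.ndarray:
        return N @ (N.T @ vec)

    archive = [p.copy() for p in points]
    center = points.mean(axis=0)
    n_seen = len(archive)
    x = center.copy()
    stored = np.empty((n_samples, n), dtype=float)
    n_stored = 0
    step = 0
    total = burn_in + n_samples * thinning
    while n_stored < n_samples:
        step += 1
        pt = archive[rng.integers(len(archive))]
        d = project(pt - center)
        norm = np.linalg.norm(d)
        if norm < _DIR_TOL:
            continue
        d /= norm
        with np.errstate(divide="ignore", invalid="ignore"):
            lo_steps = (lb - x) / d
            hi_steps = (ub - x) / d
        mask = np.abs(d) > _DIR_TOL
        lows = np.where(d > 0, lo_steps, hi_steps)[mask]
        highs = np.where(d > 0, hi_steps, lo_steps)[mask]
        alpha_min = lows.max(initial=-np.inf)
        alpha_max = highs.min(initial=np.inf)
        if not np.isfinite(alpha_min) or not np.isfinite(alpha_max) \
                or alpha_max - alpha_min < 1e-12:
            continue
        alpha = rng.uniform(alpha_min, alpha_max)
        x = x + alpha * d
        if step % _REPROJECT_EVERY == 0:
            x = project(x)
            np.clip(x, lb, ub, out=x)
            if S_dense is not None:
                drift = np.abs(S_dense @ x).max()
                if drift > _DRIFT_TOL:
                    raise cbm.SolverError(
                        f"ACHR numerical drift {drift:.2e} exceeds "
                        f"{_DRIFT_TOL:.0e}")
        archive.append(x.copy())
        center = center + (x - center) / (n_seen + 1)
        n_seen += 1
        if step > burn_in and (step - burn_in) % thinning == 0:
            out = np.clip(x, lb, ub)
            stored[n_stored] = out
            n_stored += 1
        if step > 100 * total:
            raise cbm.SolverError("ACHR failed to advance (degenerate "
                                  "geometry not detected by FVA)")
    samples = pd.DataFrame(stored, columns=list(model.reaction_ids))
    return FluxSamples(samples=samples, model_id=model.model_id, seed=seed,
                       n_samples=n_samples, burn_in=burn_in,
                       thinning=thinning, n_warmup=len(points),
                       degenerate=False)


def mean_fluxes(fs: FluxSamples) -> pd.Series:
    """Arithmetic per-reaction mean over the stored samples."""
    if len(fs.samples) < 1:
        raise ValueError("no samples stored")
    return fs.samples.mean(axis=0)
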