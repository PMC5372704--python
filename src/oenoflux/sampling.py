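"""Hit-and-run Monte Carlo sampling of the steady-state flux polytope.

The feasible set {v : S v = 0, l <= v <= u} is a convex polytope.  The
chain walks in the affine hull: directions are drawn uniformly on the
unit sphere of the null space of S (restricted to non-fixed fluxes), the
chord through the current point is intersected exactly with the bounds,
and the next point is uniform on that chord -- the classic hit-and-run
walk, whose stationary distribution is uniform over the polytope.
Thinning keeps every ``thinning_steps``-th point.  Warm-up starts from
the centroid of FVA extreme-point solutions, which lies in the polytope
by convexity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import null_space

from .fba import solve_fba
from .model import MetabolicModel, build_stoichiometric_matrix
from .variability import fva

#: |S v| and bound-violation tolerance every emitted sample must satisfy
FEASIBILITY_TOLERANCE = 1e-6


@dataclass
class SamplerConfig:
    n_points: int = 100_000
    thinning_steps: int = 500
    seed: int = 0
    warmup_points: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_points < 1 or self.thinning_steps < 1:
            raise ValueError("n_points and thinning_steps must be >= 1")


@dataclass
class SampleSet:
    samples: np.ndarray  # n_points x n_reactions
    reaction_ids: List[str]
    config: SamplerConfig
    feasibility_report: Dict[str, float] = field(default_factory=dict)


def constrain_near_optimal(
    model: MetabolicModel,
    objective: Optional[str] = None,
    fraction: float = 0.9,
) -> MetabolicModel:
    """Clamp the objective flux into [fraction * μ*, μ*]."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    sol = solve_fba(model, objective=objective)
    if not sol.optimal:
        raise RuntimeError(f"objective problem is {sol.status}")
    out = model.copy()
    rxn = out.reaction(objective or out.objective_id)
    rxn.lower_bound = fraction * sol.mu
    rxn.upper_bound = sol.mu
    return out


def _feasibility(S, lower, upper, samples) -> Dict[str, float]:
    residual = np.abs(S @ samples.T).max() if samples.size else 0.0
    below = np.maximum(lower[None, :] - samples, 0.0).max()
    above = np.maximum(samples - upper[None, :], 0.0).max()
    return {
        "max_steady_state_residual": float(residual),
        "max_bound_violation": float(max(below, above)),
    }


def hit_and_run_sample(
    model: MetabolicModel,
    config: Optional[SamplerConfig] = None,
) -> SampleSet:
    """Sample steady-state flux distributions uniformly from the polytope.

    Reproducible: identical (model, config.seed) give identical samples.
    Raises before sampling if the polytope is empty.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)

    # one LP proves the polytope non-empty and provides a fallback point
    probe = solve_fba(model, objective=model.reactions[0].id, sense="min")
    if not probe.optimal:
        raise RuntimeError(f"constrained polytope is empty ({probe.status})")

    rids = [r.id for r in model.reactions]
    lower = np.array([r.lower_bound for r in model.reactions], dtype=float)
    upper = np.array([r.upper_bound for r in model.reactions], dtype=float)
    S = build_stoichiometric_matrix(model).entries.toarray()
    n = len(rids)

    # warm-up: centroid of FVA extreme points (a feasible interior-ish start)
    n_warm = config.warmup_points
    if n_warm is None:
        n_warm = min(2 * n, 50)
    warm_targets = rids if n_warm >= 2 * n else [rids[i] for i in
                   rng.choice(n, size=max(1, n_warm // 2), replace=False)]
    _, vertices = fva(model, reactions=warm_targets, return_vertices=True)
    if vertices:
        x = np.mean(vertices, axis=0)
    else:
        x = np.array([probe.fluxes[r] for r in rids])
    x = np.clip(x, lower, upper)

    # directions live in the null space of S restricted to free fluxes
    free = upper - lower > FEASIBILITY_TOLERANCE
    fixed_vals = np.where(~free, (lower + upper) / 2.0, 0.0)
    x[~free] = fixed_vals[~free]
    if free.any():
        N = null_space(S[:, free])
    else:
        N = np.zeros((0, 0))

    samples = np.empty((config.n_points, n))
    if N.size == 0:
        # fully determined polytope: a single point
        samples[:] = x
    else:
        k = N.shape[1]
        xf = x[free]
        lf, uf = lower[free], upper[free]
        for i in range(config.n_points):
            for _ in range(config.thinning_steps):
                u = rng.normal(size=k)
                norm = np.linalg.norm(u)
                if norm == 0.0:
                    continue
                d = N @ (u / norm)
                active = np.abs(d) > 1e-12
                if not active.any():
                    continue
                t_lo = (lf[active] - xf[active]) / d[active]
                t_hi = (uf[active] - xf[active]) / d[active]
                tmin = np.minimum(t_lo, t_hi).max()
                tmax = np.maximum(t_lo, t_hi).min()
                if tmax <= tmin:
                    continue
                xf = xf + rng.uniform(tmin, tmax) * d
                np.clip(xf, lf, uf, out=xf)
            full = fixed_vals.copy()
            full[free] = xf
            samples[i] = full

    report = _feasibility(S, lower, upper, samples)
    return SampleSet(samples=samples, reaction_ids=rids, config=config,
                     feasibility_report=report)


def top_variable_reactions(
    sample_set: SampleSet,
    model: MetabolicModel,
    k: int = 50,
) -> Tuple[List[Tuple[str, float]], Counter]:
    """Reactions ranked by flux range across samples, plus the pathway
    (subsystem) frequency tally over the top k.  Ties break by id."""
    if k > len(sample_set.reaction_ids):
        raise ValueError("k exceeds the number of reactions")
    ranges = sample_set.samples.max(axis=0) - sample_set.samples.min(axis=0)
    # round away float jitter so near-ties fall back to the id order
    ranked = sorted(
        zip(sample_set.reaction_ids, ranges), key=lambda p: (-round(p[1], 9), p[0])
    )
    top = [(rid, float(rng)) for rid, rng in ranked[:k]]
    tally: Counter = Counter()
    for rid, _ in top:
        tally[model.reaction(rid).subsystem or "(unassigned)"] += 1
    return top, tally


def write_samples_tsv(sample_set: SampleSet, path) -> None:
    """Samples as a TSV matrix with a reaction-id header row."""
    with open(path, "w") as fh:
        fh.write("\t".join(sample_set.reaction_ids) + "\n")
        np.savetxt(fh, sample_set.samples, delimiter="\t", fmt="%.10g")
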