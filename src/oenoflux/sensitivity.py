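"""Scaled reduced costs of exchange reactions.

The reduced cost w of an exchange flux at its binding bound is the
marginal change of growth per unit extra exchange capacity; the scaled
reduced cost

    W = w * q / mu

(with q the flux magnitude through the exchange and mu the growth rate)
is the dimensionless elasticity: the fractional change in biomass per
fractional change in the compound's exchange rate.  Signs follow the
reporting convention of the field: positive W means relaxing the binding
bound (allowing more uptake, or more secretion when secretion-limited)
would increase growth; forced by-product secretion that drains redox
from biomass shows negative W.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .fba import FluxSolution
from .model import MetabolicModel
from .variability import fva


@dataclass
class ReducedCostRecord:
    reaction_id: str
    direction: str  # "consumed" | "produced"
    w: float  # reduced cost, h^-1 per mmol gDW^-1 h^-1
    q: float  # flux magnitude, mmol gDW^-1 h^-1
    W: float  # scaled reduced cost, dimensionless
    degenerate: Optional[bool] = None  # alternative optima at this exchange?


def scaled_reduced_costs(
    solution: FluxSolution,
    exchange_ids: Sequence[str],
    zero_tolerance: float = 1e-9,
) -> List[ReducedCostRecord]:
    """Per-exchange scaled reduced costs of an optimal solution.

    Only records with both w != 0 and W != 0 are reported; exchanges with
    non-binding bounds have w = 0 and are omitted.
    """
    if not solution.optimal:
        raise ValueError("solution is not optimal")
    mu = solution.mu
    if not mu > 0:
        raise ValueError("growth rate is zero; scaled reduced costs undefined")
    records = []
    for rid in exchange_ids:
        flux = solution.fluxes[rid]
        # dmu/d(bound value) from the solver, re-expressed per unit of
        # flux magnitude in the direction the exchange actually runs
        w_bound = solution.reduced_costs[rid]
        q = abs(flux)
        direction = "consumed" if flux < 0 else "produced"
        w = -w_bound if flux < 0 else w_bound
        W = w * q / mu
        if abs(w) <= zero_tolerance or abs(W) <= zero_tolerance:
            continue
        records.append(ReducedCostRecord(rid, direction, float(w), float(q), float(W)))
    return records


def flag_degenerate_records(
    model: MetabolicModel,
    records: List[ReducedCostRecord],
    span_tolerance: float = 1e-6,
) -> List[ReducedCostRecord]:
    """Mark records whose exchange flux is non-unique at the optimum.

    Runs FVA with the objective fixed at its optimum; a nonzero span for
    the exchange means alternative optimal bases exist and the reported
    reduced cost is basis-dependent.
    """
    if not records:
        return records
    ranges = fva(model, reactions=[r.reaction_id for r in records], fraction_of_optimum=1.0)
    spans = {fr.reaction_id: fr.span for fr in ranges}
    for rec in records:
        rec.degenerate = spans[rec.reaction_id] > span_tolerance
    return records


def summarize_across_conditions(
    per_condition: Sequence[List[ReducedCostRecord]],
) -> List[Dict[str, object]]:
    """Mean ± sample SD of w and W over several condition solves.

    Mirrors the usual report layout (reaction, direction, reduced cost
    ± spread, scaled reduced cost ± spread); the spread is the sample
    standard deviation over conditions (n-1 denominator; 0 for n=1).
    """
    by_rxn: Dict[str, List[ReducedCostRecord]] = {}
    for records in per_condition:
        for rec in records:
            by_rxn.setdefault(rec.reaction_id, []).append(rec)
    rows = []
    for rid in sorted(by_rxn):
        recs = by_rxn[rid]
        ws = np.array([r.w for r in recs])
        Ws = np.array([r.W for r in recs])
        sd = lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
        rows.append(
            {
                "reaction_id": rid,
                "direction": recs[0].direction,
                "n_conditions": len(recs),
                "w_mean": float(ws.mean()),
                "w_sd": sd(ws),
                "W_mean": float(Ws.mean()),
                "W_sd": sd(Ws),
            }
        )
    return rows
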