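"""Flux balance analysis.

Solves  max (or min)  v_obj  subject to  S v = 0,  l <= v <= u
with the HiGHS dual simplex through scipy, so that the returned optimum
is a vertex with well-defined reduced costs.  The reduced cost reported
for reaction i is dμ/db_i for its binding bound b_i: the marginal change
of the objective per unit shift of that bound value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, build_stoichiometric_matrix

#: growth below this specific growth rate (h^-1) is treated as zero
GROWTH_EPSILON = 1e-6

#: primal/dual feasibility tolerance handed to the solver
SOLVER_TOLERANCE = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


class SolverError(RuntimeError):
    """Internal solver crash (not plain infeasibility)."""


@dataclass
class FluxSolution:
    """Outcome of one LP solve.

    ``mu`` is the signed flux through the objective reaction (the specific
    growth rate, h^-1, when the objective is biomass); ``reduced_costs``
    are the duals of the active variable bounds at the returned basis.
    """

    status: str
    mu: float = float("nan")
    fluxes: Dict[str, float] = field(default_factory=dict)
    reduced_costs: Dict[str, float] = field(default_factory=dict)
    objective_id: Optional[str] = None
    solver_log: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def grows(self) -> bool:
        return self.optimal and self.mu > GROWTH_EPSILON


def _lp_arrays(model: MetabolicModel):
    S = build_stoichiometric_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return S, bounds


def solve_fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
    tolerance: float = SOLVER_TOLERANCE,
) -> FluxSolution:
    """Optimize flux through one reaction subject to S v = 0 and bounds."""
    if objective is None:
        objective = model.objective_id
    if objective is None:
        raise ValueError("no objective reaction given and the model declares none")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")

    S, bounds = _lp_arrays(model)
    if objective not in S.col_index:
        raise KeyError(f"unknown objective reaction {objective!r}")
    n = len(model.reactions)
    c = np.zeros(n)
    sign = -1.0 if sense == "max" else 1.0
    c[S.col_index[objective]] = sign

    res = _run_lp(c, S, bounds, tolerance)
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status=status, objective_id=objective, solver_log=res.message)

    rids = [r.id for r in model.reactions]
    fluxes = dict(zip(rids, res.x))
    # scipy reports d(min c'v)/d(bound); rescale to dμ/d(bound)
    w = (np.asarray(res.lower.marginals) + np.asarray(res.upper.marginals)) * sign
    reduced = dict(zip(rids, w))
    return FluxSolution(
        status="optimal",
        mu=float(res.x[S.col_index[objective]]),
        fluxes=fluxes,
        reduced_costs=reduced,
        objective_id=objective,
        solver_log=res.message,
    )


def _run_lp(c, S, bounds, tolerance):
    try:
        return linprog(
            c,
            A_eq=S.entries,
            b_eq=np.zeros(S.shape[0]),
            bounds=bounds,
            method="highs-ds",
            options={
                "primal_feasibility_tolerance": tolerance,
                "dual_feasibility_tolerance": tolerance,
            },
        )
    except Exception as exc:  # pragma: no cover - solver crash path
        raise SolverError(str(exc)) from exc


def fix_flux(
    model: MetabolicModel,
    reaction_id: str,
    value: Union[float, Tuple[float, float]],
) -> MetabolicModel:
    """Return a copy of the model with one reaction's bounds replaced.

    ``value`` is either a number (an equality constraint) or a
    ``(lower, upper)`` pair.  The input model is never modified.
    """
    if isinstance(value, tuple):
        lo, hi = value
    else:
        lo = hi = float(value)
    if lo > hi:
        raise ValueError(f"lower bound {lo} exceeds upper bound {hi}")
    out = model.copy()
    rxn = out.reaction(reaction_id)
    rxn.lower_bound = float(lo)
    rxn.upper_bound = float(hi)
    return out
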