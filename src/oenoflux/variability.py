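"""Flux variability analysis, blocked reactions and dead-end metabolites.

A reaction is blocked when it cannot carry flux in either direction even
with every exchange fully open.  A metabolite is a structural dead end
when, after expanding reversible reactions into both directions, it is
only ever produced or only ever consumed; it is a functional dead end
when neither a temporary drain nor a temporary source attached to it can
carry flux.  Structural dead ends are always functional dead ends; the
converse can fail (e.g. a metabolite trapped in an unreachable cycle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .fba import SOLVER_TOLERANCE, solve_fba
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    ReactionKind,
    StoichiometricMatrix,
    build_stoichiometric_matrix,
)

#: |flux| below this is "unable to carry flux" (solver-tolerance scale)
BLOCKED_TOLERANCE = 1e-9


@dataclass
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float

    @property
    def span(self) -> float:
        return self.max_flux - self.min_flux


@dataclass
class BlockedReport:
    blocked: Set[str]
    dead_end_metabolites: Set[str]
    blocked_with_dead_end: Set[str]


def _min_max(S, bounds, col, tol=SOLVER_TOLERANCE):
    n = len(bounds)
    c = np.zeros(n)
    out = []
    for sign in (1.0, -1.0):
        c[col] = sign
        res = linprog(
            c,
            A_eq=S.entries,
            b_eq=np.zeros(S.shape[0]),
            bounds=bounds,
            method="highs-ds",
            options={
                "primal_feasibility_tolerance": tol,
                "dual_feasibility_tolerance": tol,
            },
        )
        c[col] = 0.0
        if res.status != 0:
            raise RuntimeError(
                f"FVA subproblem for column {col} not optimal: {res.message}"
            )
        out.append(res)
    return out  # [min-solve, max-solve]


def fva(
    model: MetabolicModel,
    reactions: Optional[Sequence[str]] = None,
    fraction_of_optimum: Optional[float] = None,
    return_vertices: bool = False,
):
    """Per-reaction minimum and maximum steady-state flux.

    With ``fraction_of_optimum`` f, the objective flux is first bounded
    below by f times its optimum.  Two LPs are solved per reaction.
    """
    work = model.copy()
    if fraction_of_optimum is not None:
        if not 0 <= fraction_of_optimum <= 1:
            raise ValueError("fraction_of_optimum must lie in [0, 1]")
        base = solve_fba(work)
        if not base.optimal:
            raise RuntimeError(f"base problem is {base.status}; FVA undefined")
        obj = work.reaction(work.objective_id)
        obj.lower_bound = fraction_of_optimum * base.mu
    else:
        # still guard against an infeasible base polytope
        probe = solve_fba(work, objective=work.reactions[0].id, sense="min")
        if not probe.optimal:
            raise RuntimeError(f"base problem is {probe.status}; FVA undefined")

    S = build_stoichiometric_matrix(work)
    bounds = [(r.lower_bound, r.upper_bound) for r in work.reactions]
    targets = [r.id for r in work.reactions] if reactions is None else list(reactions)

    ranges: List[FluxRange] = []
    vertices: List[np.ndarray] = []
    for rid in targets:
        col = S.col_index[rid]
        res_min, res_max = _min_max(S, bounds, col)
        lo, hi = res_min.x[col], res_max.x[col]
        if lo > hi:  # numerical jitter on a fixed flux
            lo, hi = hi, lo
        ranges.append(FluxRange(rid, float(lo), float(hi)))
        if return_vertices:
            vertices.append(res_min.x.copy())
            vertices.append(res_max.x.copy())
    if return_vertices:
        return ranges, vertices
    return ranges


def _open_exchanges(model: MetabolicModel) -> MetabolicModel:
    out = model.copy()
    for r in out.reactions:
        if r.kind is ReactionKind.EXCHANGE:
            r.lower_bound = -DEFAULT_BOUND
            r.upper_bound = DEFAULT_BOUND
    return out


def find_blocked(model: MetabolicModel, tolerance: float = BLOCKED_TOLERANCE) -> Set[str]:
    """Reactions unable to carry flux with all exchanges fully open."""
    opened = _open_exchanges(model)
    blocked = set()
    for fr in fva(opened):
        if abs(fr.min_flux) < tolerance and abs(fr.max_flux) < tolerance:
            blocked.add(fr.reaction_id)
    return blocked


def find_dead_ends_structural(
    matrix: StoichiometricMatrix,
    reversible: Dict[str, bool],
) -> Set[str]:
    """Metabolites only produced or only consumed in S.

    ``reversible`` maps reaction id -> may the reaction run backwards;
    reversible reactions are expanded into both directions before the
    producer/consumer scan.
    """
    n_mets = matrix.shape[0]
    produced = np.zeros(n_mets, dtype=bool)
    consumed = np.zeros(n_mets, dtype=bool)
    coo = matrix.entries.tocoo()
    col_rev = np.zeros(matrix.shape[1], dtype=bool)
    for rid, j in matrix.col_index.items():
        col_rev[j] = bool(reversible.get(rid, False))
    for i, j, v in zip(coo.row, coo.col, coo.data):
        if v > 0:
            produced[i] = True
            if col_rev[j]:
                consumed[i] = True
        elif v < 0:
            consumed[i] = True
            if col_rev[j]:
                produced[i] = True
    dead = ~(produced & consumed)
    rows = {i: m for m, i in matrix.row_index.items()}
    return {rows[i] for i in np.flatnonzero(dead)}


def structural_dead_ends(model: MetabolicModel) -> Set[str]:
    """Structural dead-end scan with exchanges fully open."""
    opened = _open_exchanges(model)
    S = build_stoichiometric_matrix(opened)
    rev = {r.id: r.lower_bound < 0 for r in opened.reactions}
    return find_dead_ends_structural(S, rev)


def find_dead_ends_functional(model: MetabolicModel, tolerance: float = BLOCKED_TOLERANCE) -> Set[str]:
    """Metabolites the network cannot produce or cannot consume.

    For each metabolite a temporary drain ``M ->`` is added and maximized
    (producibility), then a temporary source ``-> M`` is added and
    maximized (consumability); a metabolite missing either capability is
    a dead end -- every reaction touching it is thereby forced to zero
    flux, and every structural dead end is also caught.  Exchanges are
    fully opened first, mirroring the blocked-reaction scan.
    """
    opened = _open_exchanges(model)
    S = build_stoichiometric_matrix(opened)
    n = S.shape[1]
    bounds = [(r.lower_bound, r.upper_bound) for r in opened.reactions]
    bounds.append((0.0, DEFAULT_BOUND))  # the temporary drain / source
    c = np.zeros(n + 1)
    c[n] = -1.0  # maximize the probe flux
    b_eq = np.zeros(S.shape[0])
    dead = set()
    for met_id, i in S.row_index.items():
        ok = True
        for sign in (-1.0, 1.0):  # drain "M ->" then source "-> M"
            col = sparse.csc_matrix(([sign], ([i], [0])), shape=(S.shape[0], 1))
            A = sparse.hstack([S.entries, col], format="csc")
            res = linprog(c, A_eq=A, b_eq=b_eq, bounds=bounds, method="highs-ds")
            if res.status != 0 or -res.fun <= tolerance:
                ok = False
                break
        if not ok:
            dead.add(met_id)
    return dead


def blocked_report(model: MetabolicModel) -> BlockedReport:
    """Blocked reactions, functional dead-end metabolites, and the
    blocked reactions touching at least one dead-end metabolite."""
    blocked = find_blocked(model)
    dead = find_dead_ends_functional(model)
    with_dead = {
        r.id
        for r in model.reactions
        if r.id in blocked and any(m in dead for m in r.stoichiometry)
    }
    return BlockedReport(blocked, dead, with_dead)


def span_histogram(
    ranges: Sequence[FluxRange],
    zero_tolerance: float = BLOCKED_TOLERANCE,
) -> Tuple[Dict[int, int], int]:
    """Counts of reactions per integer log10(span) bin.

    Zero-span reactions are excluded from the histogram and returned as a
    separate count (they are the blocked/fixed ones).
    """
    hist: Dict[int, int] = {}
    n_zero = 0
    for fr in ranges:
        if fr.span < zero_tolerance:
            n_zero += 1
            continue
        b = int(np.floor(np.log10(fr.span)))
        hist[b] = hist.get(b, 0) + 1
    return dict(sorted(hist.items())), n_zero
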