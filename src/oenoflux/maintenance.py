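"""Maintenance-ATP (NGAM) fitting and ATP-production accounting.

Non-growth-associated maintenance (NGAM) is the ATP hydrolysis flux a
cell spends on survival independently of biomass formation, represented
by the reaction

    ATP + H2O -> ADP + Pi + H+          (id ``ATPM``)

NGAM is estimated by fixing measured exchange rates, sweeping the ATPM
flux over a 0-5 mmol gDW^-1 h^-1 grid, maximizing growth at each grid
value and picking the value minimizing the relative growth-rate error
against the observed rate (coarse 0.1 sweep, then 0.01 refinement).

ATP production is accounted two ways: the network method sums the
substrate-level kinase fluxes (acetate, pyruvate and phosphoglycerate
kinases) minus the kinase ATP investments (hexokinase, fructokinase);
the classical fermentation shortcut sums D-lactate and acetate export.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .fba import FluxSolution, solve_fba
from .model import MetabolicModel, ModelIntegrityError, Reaction, ReactionKind

logger = logging.getLogger(__name__)

NGAM_REACTION_ID = "ATPM"

#: default cytosolic metabolite ids for the hydrolysis stoichiometry
NGAM_METABOLITES = {"atp": "atp_c", "h2o": "h2o_c", "adp": "adp_c", "pi": "pi_c", "h": "h_c"}

#: upper end of the maintenance sweep, mmol ATP gDW^-1 h^-1
NGAM_GRID_MAX = 5.0

ATP_ROLES = (
    "acetate_kinase",
    "pyruvate_kinase",
    "phosphoglycerate_kinase",
    "hexokinase",
    "fructokinase",
    "atp_synthase",
    "d_lactate_exchange",
    "acetate_exchange",
)


@dataclass
class RateRecord:
    reaction_id: str
    rate: float  # magnitude, mmol gDW^-1 h^-1
    direction: str  # "consumption" | "production"

    def __post_init__(self) -> None:
        if self.direction not in ("consumption", "production"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def signed_rate(self) -> float:
        """Exchange-flux convention: consumption is negative flux."""
        mag = abs(self.rate)
        return -mag if self.direction == "consumption" else mag


@dataclass
class RateConstraintSet:
    records: List[RateRecord] = field(default_factory=list)
    observed_mu: float = float("nan")


def read_rates_tsv(path) -> RateConstraintSet:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header = ["reaction_id", "rate", "direction"]
    if not lines or lines[0].split("\t") != header:
        raise ValueError(f"{path}: expected header {header}")
    records = []
    observed_mu = float("nan")
    for line in lines[1:]:
        if not line:
            continue
        rid, rate, direction = line.split("\t")
        if rid == "__observed_mu__":
            observed_mu = float(rate)
        else:
            records.append(RateRecord(rid, float(rate), direction))
    return RateConstraintSet(records, observed_mu)


def write_rates_tsv(rates: RateConstraintSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\trate\tdirection\n")
        for r in rates.records:
            fh.write(f"{r.reaction_id}\t{repr(float(r.rate))}\t{r.direction}\n")
        if not math.isnan(rates.observed_mu):
            fh.write(f"__observed_mu__\t{repr(float(rates.observed_mu))}\tproduction\n")


@dataclass
class NGAMFitResult:
    grid: List[float]
    errors: List[float]  # NaN where the constrained model was infeasible
    best_ngam: float
    predicted_mu_at_best: float

    @property
    def feasible_points(self) -> List[Tuple[float, float]]:
        return [(g, e) for g, e in zip(self.grid, self.errors) if not math.isnan(e)]


@dataclass
class ATPAccounting:
    network_rate: float
    fermentation_rate: float
    synthase_fraction: float


def add_ngam_reaction(
    model: MetabolicModel,
    metabolite_ids: Optional[Dict[str, str]] = None,
) -> MetabolicModel:
    """Return a copy carrying the ATP-hydrolysis maintenance reaction.

    Bounds start at (0, 0) -- maintenance is off until a value is set.
    Idempotent: if the reaction already exists the copy is unchanged.
    """
    out = model.copy()
    if out.has_reaction(NGAM_REACTION_ID):
        return out
    ids = dict(NGAM_METABOLITES)
    if metabolite_ids:
        ids.update(metabolite_ids)
    missing = [m for m in ids.values() if not out.has_metabolite(m)]
    if missing:
        raise ModelIntegrityError(
            f"cannot add maintenance reaction; missing metabolites: {missing}"
        )
    out.add_reaction(
        Reaction(
            id=NGAM_REACTION_ID,
            name="non-growth-associated maintenance (ATP hydrolysis)",
            stoichiometry={
                ids["atp"]: -1.0,
                ids["h2o"]: -1.0,
                ids["adp"]: 1.0,
                ids["pi"]: 1.0,
                ids["h"]: 1.0,
            },
            lower_bound=0.0,
            upper_bound=0.0,
            subsystem="ATP maintenance",
            kind=ReactionKind.NGAM,
        )
    )
    return out


def set_ngam(model: MetabolicModel, value: float) -> MetabolicModel:
    """Copy of the model with the maintenance flux fixed at ``value``."""
    out = model.copy()
    rxn = out.reaction(NGAM_REACTION_ID)
    rxn.lower_bound = rxn.upper_bound = float(value)
    return out


def apply_rates(model: MetabolicModel, rates: RateConstraintSet) -> MetabolicModel:
    """Fix measured exchange fluxes as equality bounds (lo = hi = rate)."""
    out = model.copy()
    for rec in rates.records:
        rxn = out.reaction(rec.reaction_id)
        if rxn.kind is not ReactionKind.EXCHANGE:
            raise ModelIntegrityError(
                f"measured rate for {rec.reaction_id!r}, which is not an exchange"
            )
        rxn.lower_bound = rxn.upper_bound = rec.signed_rate
    return out


def fit_ngam(
    model: MetabolicModel,
    rates: RateConstraintSet,
    grid_step: float = 0.1,
    refine_step: float = 0.01,
    grid_max: float = NGAM_GRID_MAX,
) -> NGAMFitResult:
    """Grid-sweep estimate of NGAM from measured rates and observed μ.

    Error metric: relative absolute growth-rate error
    |μ_pred - μ_obs| / μ_obs.  A coarse sweep over [0, grid_max] at
    ``grid_step`` is refined at ``refine_step`` around the coarse argmin.
    Infeasible grid points are recorded as NaN and excluded.
    """
    if not model.has_reaction(NGAM_REACTION_ID):
        raise ModelIntegrityError("model has no maintenance reaction; add it first")
    if not (rates.observed_mu > 0):
        raise ValueError("observed growth rate must be positive")
    constrained = apply_rates(model, rates)

    def sweep(values):
        errs = []
        mus = []
        for g in values:
            sol = solve_fba(set_ngam(constrained, g))
            if sol.optimal:
                mus.append(sol.mu)
                errs.append(abs(sol.mu - rates.observed_mu) / rates.observed_mu)
            else:
                mus.append(math.nan)
                errs.append(math.nan)
        return errs, mus

    coarse = [round(i * grid_step, 10) for i in range(int(round(grid_max / grid_step)) + 1)]
    errors, mus = sweep(coarse)
    feasible = [i for i, e in enumerate(errors) if not math.isnan(e)]
    if not feasible:
        raise RuntimeError("constrained model infeasible at every grid point")
    i_best = min(feasible, key=lambda i: errors[i])

    lo = max(0.0, coarse[i_best] - grid_step)
    hi = min(grid_max, coarse[i_best] + grid_step)
    fine = [round(lo + i * refine_step, 10) for i in range(int(round((hi - lo) / refine_step)) + 1)]
    fine = [g for g in fine if g not in set(coarse)]
    fine_errors, fine_mus = sweep(fine)

    grid = coarse + fine
    errors = errors + fine_errors
    mus = mus + fine_mus
    order = np.argsort(grid)
    grid = [grid[i] for i in order]
    errors = [errors[i] for i in order]
    mus = [mus[i] for i in order]

    feasible = [i for i, e in enumerate(errors) if not math.isnan(e)]
    i_best = min(feasible, key=lambda i: errors[i])
    return NGAMFitResult(
        grid=grid,
        errors=errors,
        best_ngam=grid[i_best],
        predicted_mu_at_best=mus[i_best],
    )


def atp_accounting(
    solution: FluxSolution,
    reaction_roles: Dict[str, Sequence[str]],
) -> ATPAccounting:
    """Account ATP production of an optimal flux distribution two ways.

    ``reaction_roles`` maps each role in :data:`ATP_ROLES` to the
    reaction ids playing it (possibly several, possibly none only if the
    pathway is absent -- every role key must be present).
    """
    missing = [role for role in ATP_ROLES if role not in reaction_roles]
    if missing:
        raise KeyError(f"missing reaction roles: {missing}")

    def total(role):
        return sum(solution.fluxes.get(rid, 0.0) for rid in reaction_roles[role])

    network = (
        total("acetate_kinase")
        + total("pyruvate_kinase")
        + total("phosphoglycerate_kinase")
        - total("hexokinase")
        - total("fructokinase")
    )
    fermentation = total("d_lactate_exchange") + total("acetate_exchange")
    synthase = total("atp_synthase")
    produced = network + synthase
    fraction = synthase / produced if produced > 0 else 0.0
    return ATPAccounting(
        network_rate=max(network, 0.0),
        fermentation_rate=max(fermentation, 0.0),
        synthase_fraction=min(max(fraction, 0.0), 1.0),
    )


def atp_method_discrepancy(
    pairs: Iterable[Tuple[float, float]],
) -> Tuple[float, List[float]]:
    """Mean relative shortfall (%) of the network ATP rate versus the
    D-lactate+acetate fermentation rate, over (network, fermentation)
    pairs.  Pairs with zero fermentation rate are excluded (warning)."""
    per_pair = []
    for network, fermentation in pairs:
        if fermentation == 0:
            logger.warning("ATP pair with zero fermentation rate excluded")
            continue
        per_pair.append((1.0 - network / fermentation) * 100.0)
    if not per_pair:
        raise ValueError("no usable (network, fermentation) pairs")
    return float(np.mean(per_pair)), per_pair
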