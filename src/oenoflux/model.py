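"""Core data structures for constraint-based metabolic models.

A model is a set of metabolites partitioned into two compartments
(intracellular / extracellular), a set of reactions with flux bounds in
mmol gDW^-1 h^-1 and optional gene-protein-reaction (GPR) rules, and a
biomass objective.  The steady-state constraint is S v = 0 with S the
stoichiometric matrix (rows = metabolites, columns = reactions); uptake
through an exchange reaction is negative flux, secretion positive.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional

import numpy as np
from scipy import sparse

from .gpr import genes_in_gpr

#: conventional proxy for an unbounded flux, mmol gDW^-1 h^-1
DEFAULT_BOUND = 1000.0


class ModelIntegrityError(ValueError):
    """Raised when a model violates a structural invariant."""


class Compartment(str, Enum):
    INTRACELLULAR = "intracellular"
    EXTRACELLULAR = "extracellular"


class ReactionKind(str, Enum):
    INTRACELLULAR = "intracellular"
    EXTRACELLULAR = "extracellular"
    TRANSPORT = "transport"
    EXCHANGE = "exchange"
    DEMAND = "demand"
    SINK = "sink"
    BIOMASS = "biomass"
    NGAM = "ngam"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: Compartment = Compartment.INTRACELLULAR

    def __post_init__(self) -> None:
        self.compartment = Compartment(self.compartment)


@dataclass
class Reaction:
    """A stoichiometric reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed, positive = produced).
    """

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str = ""
    kind: ReactionKind = ReactionKind.INTRACELLULAR

    def __post_init__(self) -> None:
        self.kind = ReactionKind(self.kind)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        r = Reaction(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            subsystem=self.subsystem,
            kind=self.kind,
        )
        return r


@dataclass
class Gene:
    id: str
    name: str = ""


@dataclass
class MetabolicModel:
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: List[Gene] = field(default_factory=list)
    objective_id: Optional[str] = None
    id: str = "model"

    # -- lookups -------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index()[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite id {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction id {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index()

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index()

    def _met_index(self) -> Dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> Dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.kind is ReactionKind.EXCHANGE]

    @property
    def gene_ids(self) -> List[str]:
        return [g.id for g in self.genes]

    # -- editing -------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if self.has_metabolite(met.id):
            raise ModelIntegrityError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if self.has_reaction(rxn.id):
            raise ModelIntegrityError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)

    def remove_reaction(self, rxn_id: str) -> None:
        self.reactions = [r for r in self.reactions if r.id != rxn_id]

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        """Check every structural invariant; raise ModelIntegrityError."""
        seen = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ModelIntegrityError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        met_ids = seen
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise ModelIntegrityError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
        gene_ids = set()
        for g in self.genes:
            if g.id in gene_ids:
                raise ModelIntegrityError(f"duplicate gene id {g.id!r}")
            gene_ids.add(g.id)

        mets = self._met_index()
        for r in self.reactions:
            if not r.stoichiometry:
                raise ModelIntegrityError(f"reaction {r.id!r} has empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                raise ModelIntegrityError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            for met_id, coeff in r.stoichiometry.items():
                if met_id not in met_ids:
                    raise ModelIntegrityError(
                        f"reaction {r.id!r} references undeclared metabolite {met_id!r}"
                    )
                if not np.isfinite(coeff) or coeff == 0:
                    raise ModelIntegrityError(
                        f"reaction {r.id!r}: coefficient of {met_id!r} is {coeff}"
                    )
            if r.kind is ReactionKind.EXCHANGE:
                if len(r.stoichiometry) != 1:
                    raise ModelIntegrityError(
                        f"exchange reaction {r.id!r} must touch exactly one metabolite"
                    )
                (met_id,) = r.stoichiometry
                if mets[met_id].compartment is not Compartment.EXTRACELLULAR:
                    raise ModelIntegrityError(
                        f"exchange reaction {r.id!r} touches intracellular "
                        f"metabolite {met_id!r}"
                    )
            for gid in genes_in_gpr(r.gpr):
                if gid not in gene_ids:
                    raise ModelIntegrityError(
                        f"reaction {r.id!r} GPR references undeclared gene {gid!r}"
                    )
        if self.objective_id is not None and self.objective_id not in {
            r.id for r in self.reactions
        }:
            raise ModelIntegrityError(
                f"objective id {self.objective_id!r} does not resolve to a reaction"
            )


@dataclass
class StoichiometricMatrix:
    """Sparse S with one row per metabolite and one column per reaction."""

    entries: sparse.csc_matrix
    row_index: Dict[str, int]
    col_index: Dict[str, int]

    @property
    def shape(self):
        return self.entries.shape


def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S (rows = metabolites, columns = reactions) from a model."""
    row_index = {m.id: i for i, m in enumerate(model.metabolites)}
    col_index = {r.id: j for j, r in enumerate(model.reactions)}
    rows, cols, vals = [], [], []
    for r in model.reactions:
        j = col_index[r.id]
        for met_id, coeff in r.stoichiometry.items():
            if met_id not in row_index:
                raise ModelIntegrityError(
                    f"reaction {r.id!r} references undeclared metabolite {met_id!r}"
                )
            rows.append(row_index[met_id])
            cols.append(j)
            vals.append(float(coeff))
    mat = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    return StoichiometricMatrix(entries=mat, row_index=row_index, col_index=col_index)


def metabolite_connectivity(model: MetabolicModel) -> Dict[str, int]:
    """Number of reactions each metabolite participates in."""
    counts = {m.id: 0 for m in model.metabolites}
    for r in model.reactions:
        for met_id in r.stoichiometry:
            counts[met_id] += 1
    return counts


def knockout_reactions(model: MetabolicModel, rxn_ids: Iterable[str]) -> MetabolicModel:
    """Return a copy with the given reactions pinned to zero flux."""
    out = model.copy()
    ids = set(rxn_ids)
    missing = ids - {r.id for r in out.reactions}
    if missing:
        raise KeyError(f"unknown reaction ids: {sorted(missing)}")
    for r in out.reactions:
        if r.id in ids:
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out
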