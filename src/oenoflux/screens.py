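"""Media, nutrient/carbon essentiality screens, deletions and validation.

A medium lists the nutrients whose exchange reactions may carry uptake
flux, with maximal uptake rates (mmol gDW^-1 h^-1).  Two growth criteria
are used: omission screens call no-growth when the mutant grows at less
than a fraction (default 20%) of the wild type, while sole-carbon-source
screens -- where no wild type exists -- use an absolute threshold on μ.
In-silico calls compared against in-vivo observations yield a confusion
matrix and the six derived performance metrics

    sensitivity = TP/(TP+FN)        specificity = TN/(TN+FP)
    precision   = TP/(TP+FP)        NPV         = TN/(TN+FN)
    accuracy    = (TP+TN)/total     F-score     = harmonic mean of
                                                  precision & sensitivity
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .fba import GROWTH_EPSILON, solve_fba
from .gpr import evaluate_gpr, genes_in_gpr
from .model import DEFAULT_BOUND, MetabolicModel, ReactionKind


@dataclass
class MediumComponent:
    nutrient: str
    exchange_id: str
    max_uptake: float
    always_open: bool = False

    def __post_init__(self) -> None:
        if self.max_uptake < 0:
            raise ValueError(
                f"medium component {self.nutrient!r}: max uptake must be >= 0"
            )


@dataclass
class Medium:
    components: List[MediumComponent] = field(default_factory=list)

    @property
    def exchange_ids(self) -> List[str]:
        return [c.exchange_id for c in self.components]

    def without(self, nutrient: str) -> "Medium":
        return Medium([c for c in self.components if c.nutrient != nutrient])

    def plus(self, component: MediumComponent) -> "Medium":
        return Medium(self.components + [component])

    @property
    def screenable(self) -> List[MediumComponent]:
        """Components subject to omission (always-open ones are exempt)."""
        return [c for c in self.components if not c.always_open]


def read_medium_tsv(path) -> Medium:
    header = ["nutrient", "exchange_id", "max_uptake", "always_open"]
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != header:
        raise ValueError(f"{path}: expected header {header}")
    comps = []
    for line in lines[1:]:
        if not line:
            continue
        nut, ex, up, ao = line.split("\t")
        comps.append(MediumComponent(nut, ex, float(up), ao == "1"))
    return Medium(comps)


def write_medium_tsv(medium: Medium, path) -> None:
    with open(path, "w") as fh:
        fh.write("nutrient\texchange_id\tmax_uptake\talways_open\n")
        for c in medium.components:
            fh.write(
                f"{c.nutrient}\t{c.exchange_id}\t{repr(float(c.max_uptake))}\t"
                f"{'1' if c.always_open else '0'}\n"
            )


@dataclass
class ScreenConfig:
    growth_fraction_threshold: float = 0.20
    zero_growth_epsilon: float = GROWTH_EPSILON

    def __post_init__(self) -> None:
        if not 0 < self.growth_fraction_threshold < 1:
            raise ValueError("growth_fraction_threshold must lie in (0, 1)")


@dataclass
class DeletionConfig:
    essentiality_reduction_threshold: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.essentiality_reduction_threshold < 1:
            raise ValueError("essentiality_reduction_threshold must lie in (0, 1)")


@dataclass
class GrowthCall:
    item: str
    wild_type_mu: float
    perturbed_mu: float
    call: str  # "growth" | "no_growth"

    @property
    def essential(self) -> bool:
        return self.call == "no_growth"


@dataclass
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class PerformanceMetrics:
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    accuracy: float
    f_score: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "f_score": self.f_score,
        }


# ------------------------------------------------------------- media


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Close every uptake not granted by the medium; open the granted ones.

    Exchange reactions absent from the medium get lower bound 0; listed
    ones get lower bound -max_uptake (always-open components are fully
    opened).  Secretion (upper) bounds are untouched.
    """
    out = model.copy()
    exchange_ids = {r.id for r in out.exchanges}
    missing = [c.exchange_id for c in medium.components if c.exchange_id not in exchange_ids]
    if missing:
        raise KeyError(f"medium lists non-exchange or unknown reactions: {missing}")
    uptake = {}
    for c in medium.components:
        lb = -DEFAULT_BOUND if c.always_open else -abs(c.max_uptake)
        uptake[c.exchange_id] = min(uptake.get(c.exchange_id, 0.0), lb)
    for r in out.reactions:
        if r.kind is ReactionKind.EXCHANGE:
            r.lower_bound = uptake.get(r.id, 0.0)
    return out


# ------------------------------------------------------------ screens


def single_omission_screen(
    model: MetabolicModel,
    medium: Medium,
    config: Optional[ScreenConfig] = None,
) -> List[GrowthCall]:
    """Remove each medium nutrient in turn and re-optimize growth."""
    config = config or ScreenConfig()
    wt = solve_fba(apply_medium(model, medium))
    if not wt.optimal or wt.mu <= config.zero_growth_epsilon:
        raise RuntimeError(
            "wild type does not grow on the full medium; omission screen undefined"
        )
    calls = []
    for comp in medium.screenable:
        sol = solve_fba(apply_medium(model, medium.without(comp.nutrient)))
        mu = sol.mu if sol.optimal else 0.0
        call = (
            "no_growth"
            if mu < config.growth_fraction_threshold * wt.mu
            else "growth"
        )
        calls.append(GrowthCall(comp.nutrient, wt.mu, mu, call))
    return calls


def carbon_source_screen(
    model: MetabolicModel,
    base_medium: Medium,
    sources: Sequence[MediumComponent],
    config: Optional[ScreenConfig] = None,
) -> List[GrowthCall]:
    """Test each candidate carbon source on top of a carbon-free base medium."""
    config = config or ScreenConfig()
    base = solve_fba(apply_medium(model, base_medium))
    base_mu = base.mu if base.optimal else 0.0
    if base_mu > config.zero_growth_epsilon:
        raise RuntimeError(
            "base medium sustains growth on its own; carbon-source screen confounded"
        )
    calls = []
    for src in sources:
        sol = solve_fba(apply_medium(model, base_medium.plus(src)))
        mu = sol.mu if sol.optimal else 0.0
        call = "growth" if mu > config.zero_growth_epsilon else "no_growth"
        calls.append(GrowthCall(src.nutrient, base_mu, mu, call))
    return calls


# --------------------------------------------------------- validation


def classify_outcomes(
    in_silico: Iterable[GrowthCall],
    in_vivo: Dict[str, str],
) -> Tuple[ConfusionMatrix, List[Dict[str, str]]]:
    """Tally in-silico vs in-vivo growth calls.

    TP = growth in both; TN = growth in neither; FP = in-silico growth
    only; FN = in-vivo growth only.  Every in-silico item must carry an
    in-vivo label.
    """
    calls = list(in_silico)
    missing = [c.item for c in calls if c.item not in in_vivo]
    if missing:
        raise KeyError(f"items without an in-vivo label: {missing}")
    cm = ConfusionMatrix()
    table = []
    for c in calls:
        vivo = in_vivo[c.item]
        if vivo not in ("growth", "no_growth"):
            raise ValueError(f"bad in-vivo label for {c.item!r}: {vivo!r}")
        silico = c.call
        if vivo == "growth" and silico == "growth":
            label = "TP"
            cm.tp += 1
        elif vivo == "no_growth" and silico == "no_growth":
            label = "TN"
            cm.tn += 1
        elif silico == "growth":
            label = "FP"
            cm.fp += 1
        else:
            label = "FN"
            cm.fn += 1
        table.append({"item": c.item, "in_vivo": vivo, "in_silico": silico, "label": label})
    return cm, table


def compute_metrics(cm: ConfusionMatrix) -> PerformanceMetrics:
    """The six performance metrics; undefined ratios come out as NaN."""

    def ratio(num, den):
        return num / den if den else math.nan

    sens = ratio(cm.tp, cm.tp + cm.fn)
    prec = ratio(cm.tp, cm.tp + cm.fp)
    if math.isnan(sens) or math.isnan(prec) or (prec + sens) == 0:
        f = math.nan
    else:
        f = 2 * prec * sens / (prec + sens)
    return PerformanceMetrics(
        sensitivity=sens,
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        precision=prec,
        npv=ratio(cm.tn, cm.tn + cm.fn),
        accuracy=ratio(cm.tp + cm.tn, cm.total),
        f_score=f,
    )


# ----------------------------------------------------------- deletion


def single_gene_deletion(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    config: Optional[DeletionConfig] = None,
) -> List[GrowthCall]:
    """Knock out each gene; disable reactions whose GPR goes false."""
    config = config or DeletionConfig()
    base = apply_medium(model, medium) if medium is not None else model.copy()
    wt = solve_fba(base)
    if not wt.grows:
        raise RuntimeError("wild type does not grow; deletion screen undefined")
    cutoff = (1.0 - config.essentiality_reduction_threshold) * wt.mu
    calls = []
    for gene in base.genes:
        ko = base.copy()
        for r in ko.reactions:
            if r.gpr and gene.id in genes_in_gpr(r.gpr):
                if not evaluate_gpr(r.gpr, {gene.id}):
                    r.lower_bound = 0.0
                    r.upper_bound = 0.0
        sol = solve_fba(ko)
        mu = sol.mu if sol.optimal else 0.0
        calls.append(
            GrowthCall(gene.id, wt.mu, mu, "no_growth" if mu < cutoff else "growth")
        )
    return calls


def single_reaction_deletion(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    config: Optional[DeletionConfig] = None,
) -> Tuple[List[GrowthCall], Counter]:
    """Pin each reaction to zero flux in turn; also tally essential
    reactions per subsystem (pathway distribution of essentiality)."""
    config = config or DeletionConfig()
    base = apply_medium(model, medium) if medium is not None else model.copy()
    wt = solve_fba(base)
    if not wt.grows:
        raise RuntimeError("wild type does not grow; deletion screen undefined")
    cutoff = (1.0 - config.essentiality_reduction_threshold) * wt.mu
    calls = []
    pathway_tally: Counter = Counter()
    for target in base.reactions:
        ko = base.copy()
        rxn = ko.reaction(target.id)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
        sol = solve_fba(ko)
        mu = sol.mu if sol.optimal else 0.0
        call = "no_growth" if mu < cutoff else "growth"
        calls.append(GrowthCall(target.id, wt.mu, mu, call))
        if call == "no_growth":
            pathway_tally[target.subsystem or "(unassigned)"] += 1
    return calls, pathway_tally
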