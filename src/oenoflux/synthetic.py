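"""Miniature heterofermentative lactic-acid-bacterium network generator.

The toy network emulates the wine bacterium's core physiology: hexoses
(glucose, fructose) enter the 6-phosphogluconate / phosphoketolase
pathway and ferment to D-lactate plus acetate or ethanol and CO2 with
net substrate-level ATP; fructose can instead be reduced to mannitol
(and fructose-6-P to erythritol) to regenerate the NAD+ the heterolactic
route demands; L-malate is decarboxylated to L-lactate by the malolactic
enzyme, consuming a cytosolic proton, and lactic acid diffuses out
carrying another proton -- the resulting transmembrane gradient drives a
proton-translocating ATP synthase; citrate is degraded through a lumped
citrate lyase to oxaloacetate; amino acids split into essential
(uptake-only) and synthesizable (a transamination shunt from pyruvate)
sets; a biomass reaction drains precursors and ATP and an ATP-hydrolysis
reaction represents non-growth-associated maintenance.  Slack routes a
heterofermenter plausibly owns (NADH oxidase with microaerophilic O2
uptake, acetoin overflow from pyruvate, malate dehydrogenase, amino-acid
catabolism, acyl-phosphatase, a mannitol-1-P route) keep the flux
polytope full-dimensional around the optimum so that measured exchange
rates can be pinned as equality constraints without breaking
feasibility.

Every generated model records its ground truth (planted orphan
metabolites, essential nutrients and reactions, reference optimum) for
closed-loop parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .fba import solve_fba
from .maintenance import (
    NGAM_REACTION_ID,
    RateConstraintSet,
    RateRecord,
    add_ngam_reaction,
    set_ngam,
)
from .model import (
    Compartment,
    Gene,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
)
from .screens import DeletionConfig, Medium, MediumComponent, apply_medium

#: carbon atoms per metabolite base name (cofactor pairs share a count,
#: so every mass-balanced reaction balances carbon by construction)
CARBON_COUNTS: Dict[str, int] = {
    "glc": 6, "fru": 6, "g6p": 6, "f6p": 6, "x5p": 5, "g3p": 3,
    "dpg13": 3, "pg3": 3, "pep": 3, "pyr": 3, "acp": 2, "ac": 2,
    "etoh": 2, "dlac": 3, "lac": 3, "mal": 4, "cit": 6, "oaa": 4,
    "mnl": 6, "ery": 4, "co2": 1, "actn": 4, "o2": 0,
    "atp": 10, "adp": 10, "pi": 0, "h": 0, "h2o": 0, "nad": 21, "nadh": 21,
    "nab": 21, "adeb": 10,
}

#: default maximal uptake rates of the complete medium, mmol gDW^-1 h^-1,
#: on the scale of measured rates for slow-growing wine LAB
DEFAULT_UPTAKES = {
    "glucose": 1.0,
    "fructose": 1.0,
    "L-malate": 1.0,
    "citrate": 0.5,
    "oxygen": 0.5,
    "amino_acid_essential": 0.5,
    "amino_acid_synthesizable": 2.0,
}

#: measured species of synthetic rate datasets: sugars and organic acids
#: consumed, fermentation products secreted, essential amino acids consumed
MEASURED_CONSUMED = ("EX_glc", "EX_fru", "EX_mal", "EX_cit")
MEASURED_PRODUCED = ("EX_dlac", "EX_lac", "EX_ac", "EX_etoh", "EX_mnl", "EX_ery")

#: ATP-accounting roles of the toy network's reactions
TOY_ATP_ROLES = {
    "acetate_kinase": ["ACK"],
    "pyruvate_kinase": ["PYK"],
    "phosphoglycerate_kinase": ["PGK"],
    "hexokinase": ["HEX"],
    "fructokinase": ["FRK"],
    "atp_synthase": ["ATPS"],
    "d_lactate_exchange": ["EX_dlac"],
    "acetate_exchange": ["EX_ac"],
}


@dataclass
class ToyNetworkConfig:
    seed: int = 0
    include_malolactic: bool = True
    include_citrate: bool = True
    n_essential_amino_acids: int = 3
    n_synthesizable_amino_acids: int = 2
    protons_per_atp: int = 3
    mannitol_branch: bool = True
    erythritol_branch: bool = True
    planted_orphan_metabolites: int = 0

    def __post_init__(self) -> None:
        if self.n_essential_amino_acids < 0 or self.n_synthesizable_amino_acids < 0:
            raise ValueError("amino-acid counts must be >= 0")
        if self.planted_orphan_metabolites < 0:
            raise ValueError("planted_orphan_metabolites must be >= 0")
        if self.protons_per_atp < 1:
            raise ValueError("protons_per_atp must be a positive integer")


@dataclass
class GroundTruth:
    true_ngam: float = 0.0
    essential_nutrients: Set[str] = field(default_factory=set)
    essential_reactions: Set[str] = field(default_factory=set)
    orphan_metabolites: Set[str] = field(default_factory=set)
    optimal_mu: float = float("nan")


def carbon_count(met_id: str) -> int:
    """Carbon atoms of a generated metabolite (by its base name)."""
    base = met_id.rsplit("_", 1)[0]
    if base.startswith("aaE") or base.startswith("aaS") or base.startswith("orph"):
        return {"aaE": 5, "aaS": 3, "orph": 3}[base[:4].rstrip("0123456789")]
    return CARBON_COUNTS[base]


def _build(config: ToyNetworkConfig) -> MetabolicModel:
    m = MetabolicModel(id="toy_lab")
    C, E = Compartment.INTRACELLULAR, Compartment.EXTRACELLULAR

    def met(mid, comp, name=""):
        m.add_metabolite(Metabolite(mid, name=name or mid, compartment=comp))

    def rxn(rid, stoich, lb, ub, gpr="", subsystem="", kind=ReactionKind.INTRACELLULAR, name=""):
        m.add_reaction(
            Reaction(rid, name=name or rid, stoichiometry=stoich, lower_bound=lb,
                     upper_bound=ub, gpr=gpr, subsystem=subsystem, kind=kind)
        )

    def exchange(mid, lb, ub=1000.0):
        rxn(f"EX_{mid[:-2]}", {mid: -1.0}, lb, ub, subsystem="Exchange",
            kind=ReactionKind.EXCHANGE)

    # -- metabolite inventory -----------------------------------------
    core_c = ["glc", "fru", "g6p", "f6p", "x5p", "g3p", "dpg13", "pg3", "pep",
              "pyr", "acp", "ac", "etoh", "dlac", "actn", "co2", "o2",
              "atp", "adp", "pi", "h", "h2o", "nad", "nadh", "nab", "adeb"]
    core_e = ["glc", "fru", "dlac", "ac", "etoh", "actn", "co2", "o2", "h", "h2o",
              "pi", "nab", "adeb"]
    if config.include_malolactic:
        core_c += ["mal", "lac", "oaa"]
        core_e += ["mal", "lac"]
    if config.include_citrate:
        core_c += ["cit"]
        core_e += ["cit"]
        if "oaa" not in core_c:
            core_c += ["oaa"]
    if config.mannitol_branch:
        core_c += ["mnl"]
        core_e += ["mnl"]
    if config.erythritol_branch:
        core_c += ["ery"]
        core_e += ["ery"]
    for b in core_c:
        met(f"{b}_c", C)
    for b in core_e:
        met(f"{b}_e", E)

    up = DEFAULT_UPTAKES

    # -- hexose uptake and phosphoketolase backbone -------------------
    rxn("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000, "glcT", "Membrane transport",
        ReactionKind.TRANSPORT, "glucose permease")
    rxn("FRUt", {"fru_e": -1, "fru_c": 1}, 0, 1000, "fruT", "Membrane transport",
        ReactionKind.TRANSPORT, "fructose permease")
    rxn("HEX", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1},
        0, 1000, "hexA", "Hexose phosphorylation", name="hexokinase")
    rxn("FRK", {"fru_c": -1, "atp_c": -1, "f6p_c": 1, "adp_c": 1, "h_c": 1},
        0, 1000, "frkA", "Hexose phosphorylation", name="fructokinase")
    rxn("PGI", {"g6p_c": -1, "f6p_c": 1}, -1000, 1000, "pgiA",
        "Hexose phosphorylation", name="phosphoglucose isomerase")
    rxn("OPPP", {"g6p_c": -1, "nad_c": -2, "h2o_c": -1,
                 "x5p_c": 1, "co2_c": 1, "nadh_c": 2, "h_c": 2},
        0, 1000, "zwfA and gndA", "Phosphoketolase pathway",
        name="6-phosphogluconate oxidative branch (lumped)")
    rxn("PKT", {"x5p_c": -1, "pi_c": -1, "g3p_c": 1, "acp_c": 1, "h2o_c": 1},
        0, 1000, "xpkA", "Phosphoketolase pathway", name="phosphoketolase")
    rxn("GAPD", {"g3p_c": -1, "pi_c": -1, "nad_c": -1,
                 "dpg13_c": 1, "nadh_c": 1, "h_c": 1},
        0, 1000, "gapA", "Glycolysis lower branch",
        name="glyceraldehyde-3-P dehydrogenase")
    rxn("PGK", {"dpg13_c": -1, "adp_c": -1, "pg3_c": 1, "atp_c": 1},
        0, 1000, "pgkA", "Glycolysis lower branch", name="phosphoglycerate kinase")
    rxn("ENO", {"pg3_c": -1, "pep_c": 1, "h2o_c": 1},
        0, 1000, "enoA", "Glycolysis lower branch", name="enolase (lumped with PGM)")
    rxn("PYK", {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1},
        0, 1000, "pykA", "Glycolysis lower branch", name="pyruvate kinase")

    # -- fermentative branches ----------------------------------------
    rxn("LDH", {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "dlac_c": 1, "nad_c": 1},
        0, 1000, "ldhD1 or ldhD2", "Fermentation", name="D-lactate dehydrogenase")
    rxn("ACK", {"acp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1},
        0, 1000, "ackA", "Fermentation", name="acetate kinase")
    rxn("ADHE", {"acp_c": -1, "nadh_c": -2, "h_c": -2,
                 "etoh_c": 1, "pi_c": 1, "nad_c": 2},
        0, 1000, "adhE", "Fermentation",
        name="ethanol branch (phosphotransacetylase + dehydrogenases, lumped)")
    rxn("ACP_HYD", {"acp_c": -1, "h2o_c": -1, "ac_c": 1, "pi_c": 1},
        0, 1000, "", "Fermentation", name="acyl phosphatase (spontaneous)")
    rxn("ALS", {"pyr_c": -2, "h_c": -1, "actn_c": 1, "co2_c": 2},
        0, 1000, "alsS", "Pyruvate overflow",
        name="acetolactate synthase/decarboxylase to acetoin (lumped)")
    rxn("NOX", {"nadh_c": -2, "h_c": -2, "o2_c": -1, "nad_c": 2, "h2o_c": 2},
        0, 1000, "noxA", "Oxygen metabolism", name="NADH oxidase (water-forming)")
    rxn("O2t", {"o2_e": -1, "o2_c": 1}, 0, 1000, "", "Membrane transport",
        ReactionKind.TRANSPORT, "oxygen diffusion")

    if config.mannitol_branch:
        rxn("MTLD", {"fru_c": -1, "nadh_c": -1, "h_c": -1, "mnl_c": 1, "nad_c": 1},
            0, 1000, "mdhM", "Mannitol biosynthesis", name="mannitol dehydrogenase")
        rxn("MTL1P", {"f6p_c": -1, "nadh_c": -1, "h_c": -1, "h2o_c": -1,
                      "mnl_c": 1, "nad_c": 1, "pi_c": 1},
            0, 1000, "mtlD", "Mannitol biosynthesis",
            name="mannitol-1-phosphate route (lumped)")
        rxn("MNLt", {"mnl_c": -1, "mnl_e": 1}, 0, 1000, "", "Membrane transport",
            ReactionKind.TRANSPORT)
    if config.erythritol_branch:
        rxn("ERYS", {"f6p_c": -1, "nadh_c": -1, "h_c": -1,
                     "ery_c": 1, "acp_c": 1, "nad_c": 1},
            0, 1000, "eryA and eryB", "Erythritol biosynthesis",
            name="erythritol branch via erythrose-4-P (lumped)")
        rxn("ERYt", {"ery_c": -1, "ery_e": 1}, 0, 1000, "", "Membrane transport",
            ReactionKind.TRANSPORT)

    # -- malolactic fermentation and citrate --------------------------
    if config.include_malolactic:
        rxn("MALt", {"mal_e": -1, "mal_c": 1}, 0, 1000, "mleP", "Membrane transport",
            ReactionKind.TRANSPORT, "malate permease")
        rxn("MLE", {"mal_c": -1, "h_c": -1, "lac_c": 1, "co2_c": 1},
            0, 1000, "mleA", "Malolactic fermentation",
            name="malolactic enzyme (proton-consuming decarboxylation)")
        rxn("MDH", {"mal_c": -1, "nad_c": -1, "oaa_c": 1, "nadh_c": 1, "h_c": 1},
            0, 1000, "mdhA", "Malolactic fermentation", name="malate dehydrogenase")
        rxn("LLDH", {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac_c": 1, "nad_c": 1},
            0, 1000, "ldhL", "Fermentation", name="L-lactate dehydrogenase")
        rxn("LACt", {"lac_c": -1, "h_c": -1, "lac_e": 1, "h_e": 1},
            0, 1000, "latP", "Membrane transport", ReactionKind.TRANSPORT,
            "lactic acid efflux (proton-extruding)")
    if config.include_citrate:
        rxn("CITt", {"cit_e": -1, "cit_c": 1}, 0, 1000, "citP", "Membrane transport",
            ReactionKind.TRANSPORT, "citrate permease")
        rxn("CITL", {"cit_c": -1, "oaa_c": 1, "ac_c": 1},
            0, 1000, "citD and citE and citF", "Citrate degradation",
            name="citrate lyase complex (lumped)")
    if config.include_malolactic or config.include_citrate:
        rxn("OAADC", {"oaa_c": -1, "h_c": -1, "pyr_c": 1, "co2_c": 1},
            0, 1000, "oadA", "Citrate degradation", name="oxaloacetate decarboxylase")

    # -- proton economy ------------------------------------------------
    n_h = config.protons_per_atp
    atps = {"adp_c": -1.0, "pi_c": -1.0, "h_e": -float(n_h),
            "atp_c": 1.0, "h2o_c": 1.0}
    if n_h > 1:
        atps["h_c"] = float(n_h - 1)
    rxn("ATPS", atps, 0, 1000, "atpA and atpB and atpC",
        "Proton-motive force", name=f"F0F1 ATP synthase ({n_h} H+ per ATP)")
    rxn("DLACt", {"dlac_c": -1, "h_c": -1, "dlac_e": 1, "h_e": 1},
        0, 1000, "", "Membrane transport", ReactionKind.TRANSPORT,
        "D-lactic acid efflux (proton-extruding)")
    rxn("CO2t_h", {"co2_c": -1, "h_c": -1, "co2_e": 1, "h_e": 1},
        0, 1000, "", "Membrane transport", ReactionKind.TRANSPORT,
        "carbonic-acid efflux (proton-extruding)")
    rxn("CO2t", {"co2_c": -1, "co2_e": 1}, 0, 1000, "", "Membrane transport",
        ReactionKind.TRANSPORT, "CO2 diffusion")
    rxn("PLEAK", {"h_e": -1, "h_c": 1}, 0, 1000, "", "Membrane transport",
        ReactionKind.TRANSPORT, "proton leak (inward)")
    rxn("ACt", {"ac_c": -1, "ac_e": 1}, 0, 1000, "", "Membrane transport",
        ReactionKind.TRANSPORT)
    rxn("ETOHt", {"etoh_c": -1, "etoh_e": 1}, 0, 1000, "", "Membrane transport",
        ReactionKind.TRANSPORT)
    rxn("ACTNt", {"actn_c": -1, "actn_e": 1}, 0, 1000, "", "Membrane transport",
        ReactionKind.TRANSPORT)
    rxn("H2Ot", {"h2o_c": -1, "h2o_e": 1}, -1000, 1000, "", "Membrane transport",
        ReactionKind.TRANSPORT)

    # -- cofactor salvage (keeps the P / nicotinamide / adenylate pools
    #    open to the environment, as genome-scale reconstructions are) --
    rxn("PIt", {"pi_e": -1, "pi_c": 1}, -1000, 1000, "", "Membrane transport",
        ReactionKind.TRANSPORT, "phosphate transport")
    rxn("NABt", {"nab_e": -1, "nab_c": 1}, -1000, 1000, "", "Membrane transport",
        ReactionKind.TRANSPORT, "nicotinamide-precursor transport")
    rxn("NADS", {"nab_c": -1, "nad_c": 1}, 0, 1000, "nadS", "Cofactor salvage",
        name="NAD salvage synthesis")
    rxn("NADD", {"nad_c": -1, "nab_c": 1}, 0, 1000, "", "Cofactor salvage",
        name="NAD turnover")
    rxn("ADEBt", {"adeb_e": -1, "adeb_c": 1}, -1000, 1000, "", "Membrane transport",
        ReactionKind.TRANSPORT, "adenylate-precursor transport")
    rxn("ADNS", {"adeb_c": -1, "adp_c": 1}, 0, 1000, "adkA", "Cofactor salvage",
        name="adenylate salvage synthesis")
    rxn("ADND", {"adp_c": -1, "adeb_c": 1}, 0, 1000, "", "Cofactor salvage",
        name="adenylate turnover")

    # -- amino acids ----------------------------------------------------
    biomass_stoich: Dict[str, float] = {}
    for i in range(1, config.n_essential_amino_acids + 1):
        met(f"aaE{i}_c", C, f"essential amino acid {i}")
        met(f"aaE{i}_e", E, f"essential amino acid {i}")
        rxn(f"AAEt{i}", {f"aaE{i}_e": -1, f"aaE{i}_c": 1}, 0, 1000, f"eaaT{i}",
            "Membrane transport", ReactionKind.TRANSPORT)
        rxn(f"AADEG{i}", {f"aaE{i}_c": -1, "adp_c": -1, "pi_c": -1, "nad_c": -2,
                          "h2o_c": -3, "co2_c": 5, "nadh_c": 2, "atp_c": 1, "h_c": 2},
            0, 1000, f"eaaD{i}", "Amino acid catabolism",
            name=f"amino acid {i} oxidative catabolism (deiminase-like, +ATP)")
        exchange(f"aaE{i}_e", -up["amino_acid_essential"])
        biomass_stoich[f"aaE{i}_c"] = -0.05
    for i in range(1, config.n_synthesizable_amino_acids + 1):
        met(f"aaS{i}_c", C, f"synthesizable amino acid {i}")
        met(f"aaS{i}_e", E, f"synthesizable amino acid {i}")
        rxn(f"AASt{i}", {f"aaS{i}_e": -1, f"aaS{i}_c": 1}, 0, 1000, f"saaT{i}",
            "Membrane transport", ReactionKind.TRANSPORT)
        rxn(f"AAS{i}", {"pyr_c": -1, "nadh_c": -1, "h_c": -1,
                        f"aaS{i}_c": 1, "nad_c": 1},
            0, 1000, f"saaS{i}", "Amino acid biosynthesis",
            name=f"amino acid {i} transamination shunt from pyruvate")
        exchange(f"aaS{i}_e", -up["amino_acid_synthesizable"])
        biomass_stoich[f"aaS{i}_c"] = -0.5

    # -- orphan metabolites (planted structural dead ends) -------------
    for i in range(1, config.planted_orphan_metabolites + 1):
        met(f"orph{i}_c", C, f"orphan metabolite {i}")
        rxn(f"ORPHSYN{i}", {"pyr_c": -1, f"orph{i}_c": 1}, 0, 1000, "",
            "Orphan reactions", name=f"orphan metabolite {i} synthesis")

    # -- biomass ---------------------------------------------------------
    # amino-acid dominated composition with a 10 mmol/gDW ATP demand (the
    # growth-associated maintenance surrogate); carbon enters biomass via
    # the amino-acid pools, sugars are primarily the energy source.  Small
    # net demands for phosphate, adenylate and NAD (nucleic-acid/cofactor
    # content) keep the salvage routes flux-bearing.
    biomass_stoich.update({"atp_c": -10.0, "h2o_c": -10.0, "nad_c": -0.05,
                           "adp_c": 9.9, "pi_c": 9.5, "h_c": 10.0})
    rxn("BIOMASS", biomass_stoich, 0, 1000, "", "Biomass",
        ReactionKind.BIOMASS, "biomass assembly (amino acids + ATP)")
    m.objective_id = "BIOMASS"

    # -- exchanges -------------------------------------------------------
    exchange("glc_e", -up["glucose"])
    exchange("fru_e", -up["fructose"])
    exchange("o2_e", -up["oxygen"])
    if config.include_malolactic:
        exchange("mal_e", -up["L-malate"])
        exchange("lac_e", 0.0)
    if config.include_citrate:
        exchange("cit_e", -up["citrate"])
    for b in ("dlac", "ac", "etoh", "actn", "co2", "h"):
        exchange(f"{b}_e", 0.0)
    if config.mannitol_branch:
        exchange("mnl_e", 0.0)
    if config.erythritol_branch:
        exchange("ery_e", 0.0)
    exchange("h2o_e", -1000.0)
    exchange("pi_e", -1000.0)
    exchange("nab_e", -1.0)
    exchange("adeb_e", -1.0)

    # -- genes ------------------------------------------------------------
    from .gpr import genes_in_gpr

    gene_ids = sorted({g for r in m.reactions for g in genes_in_gpr(r.gpr)})
    m.genes = [Gene(gid) for gid in gene_ids]
    return m


def default_medium(config: Optional[ToyNetworkConfig] = None) -> Medium:
    """The complete growth medium matching the generator's defaults."""
    config = config or ToyNetworkConfig()
    up = DEFAULT_UPTAKES
    comps = [
        MediumComponent("glucose", "EX_glc", up["glucose"]),
        MediumComponent("fructose", "EX_fru", up["fructose"]),
        MediumComponent("oxygen", "EX_o2", up["oxygen"]),
        MediumComponent("nicotinate", "EX_nab", 1.0),
        MediumComponent("adenine", "EX_adeb", 1.0),
        MediumComponent("water", "EX_h2o", 1000.0, always_open=True),
        MediumComponent("phosphate", "EX_pi", 1000.0, always_open=True),
    ]
    if config.include_malolactic:
        comps.append(MediumComponent("L-malate", "EX_mal", up["L-malate"]))
    if config.include_citrate:
        comps.append(MediumComponent("citrate", "EX_cit", up["citrate"]))
    for i in range(1, config.n_essential_amino_acids + 1):
        comps.append(
            MediumComponent(f"amino_acid_E{i}", f"EX_aaE{i}",
                            up["amino_acid_essential"])
        )
    for i in range(1, config.n_synthesizable_amino_acids + 1):
        comps.append(
            MediumComponent(f"amino_acid_S{i}", f"EX_aaS{i}",
                            up["amino_acid_synthesizable"])
        )
    return Medium(comps)


def make_toy_lab_model(
    config: Optional[ToyNetworkConfig] = None,
    compute_essentials: bool = True,
) -> Tuple[MetabolicModel, GroundTruth]:
    """Generate the toy LAB model plus its recorded ground truth.

    The model ships with the maintenance reaction (bounds (0, 0)) and
    exchange bounds matching :func:`default_medium`.  Ground-truth
    essential reactions are established by exhaustive single-reaction
    re-solves at generation time.
    """
    config = config or ToyNetworkConfig()
    model = _build(config)
    model = add_ngam_reaction(model)
    model.validate()

    truth = GroundTruth()
    truth.orphan_metabolites = {
        f"orph{i}_c" for i in range(1, config.planted_orphan_metabolites + 1)
    }
    truth.essential_nutrients = {
        f"amino_acid_E{i}" for i in range(1, config.n_essential_amino_acids + 1)
    } | {"nicotinate", "adenine"}
    ref = solve_fba(model)
    if not ref.optimal:
        raise RuntimeError(f"generated model does not solve: {ref.status}")
    truth.optimal_mu = ref.mu

    if compute_essentials:
        cutoff = (1 - DeletionConfig().essentiality_reduction_threshold) * ref.mu
        ko = model.copy()
        for target in ko.reactions:
            saved = (target.lower_bound, target.upper_bound)
            target.lower_bound = target.upper_bound = 0.0
            sol = solve_fba(ko)
            mu = sol.mu if sol.optimal else 0.0
            if mu < cutoff:
                truth.essential_reactions.add(target.id)
            target.lower_bound, target.upper_bound = saved
    return model, truth


def make_reduced_toy_model(with_branch: bool = True) -> MetabolicModel:
    """A <= 10-reaction fermentation core for brute-force LP oracles."""
    m = MetabolicModel(id="toy_reduced")
    C, E = Compartment.INTRACELLULAR, Compartment.EXTRACELLULAR
    for mid, comp in [("glc_e", E), ("glc_c", C), ("pyr_c", C), ("dlac_c", C),
                      ("dlac_e", E), ("atp_c", C), ("adp_c", C)]:
        m.add_metabolite(Metabolite(mid, compartment=comp))
    m.add_reaction(Reaction("EX_glc", stoichiometry={"glc_e": -1}, lower_bound=-10,
                            upper_bound=0, kind=ReactionKind.EXCHANGE))
    m.add_reaction(Reaction("GLCt", stoichiometry={"glc_e": -1, "glc_c": 1},
                            lower_bound=0, upper_bound=1000,
                            kind=ReactionKind.TRANSPORT))
    m.add_reaction(Reaction("CAT", name="lumped catabolism",
                            stoichiometry={"glc_c": -1, "adp_c": -2,
                                           "pyr_c": 2, "atp_c": 2},
                            lower_bound=0, upper_bound=1000))
    m.add_reaction(Reaction("LDH", stoichiometry={"pyr_c": -1, "dlac_c": 1},
                            lower_bound=0, upper_bound=1000))
    m.add_reaction(Reaction("DLACt", stoichiometry={"dlac_c": -1, "dlac_e": 1},
                            lower_bound=0, upper_bound=1000,
                            kind=ReactionKind.TRANSPORT))
    m.add_reaction(Reaction("EX_dlac", stoichiometry={"dlac_e": -1},
                            lower_bound=0, upper_bound=1000,
                            kind=ReactionKind.EXCHANGE))
    m.add_reaction(Reaction("BIOMASS", stoichiometry={"pyr_c": -1, "atp_c": -2,
                                                      "adp_c": 2},
                            lower_bound=0, upper_bound=1000,
                            kind=ReactionKind.BIOMASS))
    if with_branch:
        m.add_metabolite(Metabolite("ac_e", compartment=E))
        m.add_reaction(Reaction("ACKt", name="acetate branch (lumped, +ATP)",
                                stoichiometry={"pyr_c": -1, "adp_c": -1,
                                               "ac_e": 1, "atp_c": 1},
                                lower_bound=0, upper_bound=1000))
        m.add_reaction(Reaction("EX_ac", stoichiometry={"ac_e": -1},
                                lower_bound=0, upper_bound=1000,
                                kind=ReactionKind.EXCHANGE))
    m.objective_id = "BIOMASS"
    m.validate()
    return m


def random_toy_config(seed: int) -> ToyNetworkConfig:
    """A seeded random variation of the toy network for property tests."""
    rng = np.random.default_rng(seed)
    return ToyNetworkConfig(
        seed=seed,
        include_malolactic=bool(rng.integers(2)),
        include_citrate=bool(rng.integers(2)),
        n_essential_amino_acids=int(rng.integers(1, 4)),
        n_synthesizable_amino_acids=int(rng.integers(0, 3)),
        protons_per_atp=int(rng.integers(2, 5)),
        mannitol_branch=bool(rng.integers(2)),
        erythritol_branch=bool(rng.integers(2)),
        planted_orphan_metabolites=int(rng.integers(0, 4)),
    )


def make_synthetic_rates(
    model: MetabolicModel,
    true_ngam: float,
    noise_sd_rel: float = 0.0,
    seed: int = 0,
) -> Tuple[RateConstraintSet, GroundTruth]:
    """Exchange-rate dataset generated from the model at a known NGAM.

    The maintenance flux is fixed at ``true_ngam``, growth is maximized,
    and the optimal fluxes through the measured exchanges (sugars,
    organic acids, essential amino acids, fermentation products) become
    the "measured" rates.  Multiplicative Gaussian noise of relative SD
    ``noise_sd_rel`` is applied to the substrate rates; the product
    rates are then re-extracted from a re-solve under the noised
    substrate rates, so that the noised dataset stays mass-consistent
    (independent jitter on every rate of a network this small almost
    surely violates its stoichiometric couplings and yields an empty
    polytope).  The observed growth rate is the noiseless optimum.
    """
    if not model.has_reaction(NGAM_REACTION_ID):
        raise ValueError("model has no maintenance reaction")
    if not 0 <= true_ngam <= 5:
        raise ValueError("true_ngam must lie in [0, 5]")
    at_ngam = set_ngam(model, true_ngam)
    sol = solve_fba(at_ngam)
    if not sol.optimal:
        raise RuntimeError(f"model infeasible at maintenance {true_ngam}")
    rng = np.random.default_rng(seed)

    consumed = [rid for rid in MEASURED_CONSUMED if model.has_reaction(rid)]
    consumed += [
        f"EX_aaE{i + 1}"
        for i in range(sum(1 for x in model.reactions if x.id.startswith("AAEt")))
    ]
    produced = [rid for rid in MEASURED_PRODUCED if model.has_reaction(rid)]

    records: List[RateRecord] = []
    substrate_rates = {}
    for rid in consumed:
        rate = abs(sol.fluxes[rid])
        if noise_sd_rel > 0:
            rate = max(rate * (1.0 + rng.normal(0.0, noise_sd_rel)), 0.0)
        substrate_rates[rid] = rate
        records.append(RateRecord(rid, rate, "consumption"))

    product_source = sol
    if noise_sd_rel > 0:
        noised = at_ngam.copy()
        for rid, rate in substrate_rates.items():
            rxn = noised.reaction(rid)
            rxn.lower_bound = rxn.upper_bound = -rate
        product_source = solve_fba(noised)
        if not product_source.optimal:
            raise RuntimeError("noised substrate rates yield an empty polytope")
    for rid in produced:
        records.append(RateRecord(rid, abs(product_source.fluxes[rid]), "production"))

    rates = RateConstraintSet(records=records, observed_mu=sol.mu)
    truth = GroundTruth(true_ngam=true_ngam, optimal_mu=sol.mu)
    return rates, truth


# ------------------------------------------------------- validation table


def load_validation_table() -> pd.DataFrame:
    """The packaged nutritional-requirement validation table.

    62 nutrients (18 carbon sources, 20 amino acids, 6 nucleotides,
    7 minerals, 11 vitamins) with observed (in vivo) and predicted
    (in silico) growth calls and the printed TP/TN/FP/FN label.
    """
    with resources.files("oenoflux.data").joinpath("validation_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def validation_calls() -> Tuple[List, Dict[str, str]]:
    """The fixture re-expressed as growth calls + in-vivo labels."""
    from .screens import GrowthCall

    df = load_validation_table()
    to_call = lambda flag: "growth" if flag == "+" else "no_growth"
    calls = [
        GrowthCall(item=row.item, wild_type_mu=float("nan"),
                   perturbed_mu=float("nan"), call=to_call(row.in_silico))
        for row in df.itertuples()
    ]
    in_vivo = {row.item: to_call(row.in_vivo) for row in df.itertuples()}
    return calls, in_vivo
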