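"""End-to-end analysis pipeline with a reproducible report bundle.

Stages run in a fixed order -- load/validate, growth optimization, flux
variability + blocked/dead-end scan, nutrient screens (when a medium is
given), maintenance fit + ATP accounting + exchange sensitivity (when
measured rates are given), flux sampling (when requested) -- and every
artifact lands in the output directory together with a manifest
recording inputs, seeds, versions and wall-clock times.  A stage failure
aborts the run with the stage name and a machine-readable code; outputs
of completed stages are kept.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .fba import solve_fba
from .io import read_model
from .maintenance import ATP_ROLES, atp_accounting, fit_ngam, read_rates_tsv
from .model import MetabolicModel
from .sampling import SamplerConfig, hit_and_run_sample, top_variable_reactions
from .screens import (
    DeletionConfig,
    ScreenConfig,
    apply_medium,
    read_medium_tsv,
    single_omission_screen,
    single_reaction_deletion,
)
from .sensitivity import scaled_reduced_costs
from .variability import blocked_report, fva

#: machine-readable stage failure codes
ERROR_CODES = {"validation": 2, "infeasible": 3, "io": 4}


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code
        self.exit_code = ERROR_CODES.get(code, 1)


@dataclass
class RunConfig:
    model_path: str
    output_dir: str
    medium_path: Optional[str] = None
    rates_path: Optional[str] = None
    seed: int = 0
    sample: bool = False
    sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(n_points=1000, thinning_steps=50))
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    deletion: DeletionConfig = field(default_factory=DeletionConfig)
    atp_roles: Optional[Dict[str, List[str]]] = None


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "version": __version__,
        "inputs": {
            "model": config.model_path,
            "medium": config.medium_path,
            "rates": config.rates_path,
        },
        "seed": config.seed,
        "stages": {},
        "artifacts": [],
    }

    def stage(name):
        manifest["stages"][name] = {"started": time.time()}

        def done(**info):
            rec = manifest["stages"][name]
            rec["seconds"] = round(time.time() - rec.pop("started"), 3)
            rec.update(info)

        return done

    def artifact(path: Path):
        manifest["artifacts"].append(str(path.name))

    # ---- load & validate ------------------------------------------
    done = stage("load")
    try:
        model = read_model(config.model_path)
    except FileNotFoundError as exc:
        raise StageError("load", "io", str(exc)) from exc
    except Exception as exc:
        raise StageError("load", "validation", str(exc)) from exc
    done(reactions=len(model.reactions), metabolites=len(model.metabolites))

    medium = None
    if config.medium_path:
        medium = read_medium_tsv(config.medium_path)
        model_m = apply_medium(model, medium)
    else:
        model_m = model

    # ---- FBA -------------------------------------------------------
    done = stage("fba")
    sol = solve_fba(model_m)
    if not sol.optimal:
        raise StageError("fba", "infeasible", f"growth problem is {sol.status}")
    p = out / "fba_fluxes.tsv"
    with open(p, "w") as fh:
        fh.write("reaction\tflux\treduced_cost\n")
        for rid in sorted(sol.fluxes):
            fh.write(f"{rid}\t{sol.fluxes[rid]:.10g}\t{sol.reduced_costs[rid]:.10g}\n")
    artifact(p)
    done(mu=sol.mu)

    # ---- FVA + blocked + dead ends --------------------------------
    done = stage("variability")
    ranges = fva(model_m)
    report = blocked_report(model)
    p = out / "fva.tsv"
    with open(p, "w") as fh:
        fh.write("reaction\tmin_flux\tmax_flux\tspan\tblocked\n")
        for fr in ranges:
            fh.write(
                f"{fr.reaction_id}\t{fr.min_flux:.10g}\t{fr.max_flux:.10g}\t"
                f"{fr.span:.10g}\t{int(fr.reaction_id in report.blocked)}\n"
            )
    artifact(p)
    p = out / "blocked.json"
    _write_json(
        p,
        {
            "blocked": sorted(report.blocked),
            "dead_end_metabolites": sorted(report.dead_end_metabolites),
            "blocked_with_dead_end": sorted(report.blocked_with_dead_end),
        },
    )
    artifact(p)
    done(n_blocked=len(report.blocked), n_dead_ends=len(report.dead_end_metabolites))

    # ---- screens ---------------------------------------------------
    if medium is not None:
        done = stage("screens")
        omission = single_omission_screen(model, medium, config.screen)
        deletions, pathways = single_reaction_deletion(model, medium, config.deletion)
        p = out / "omission_screen.tsv"
        with open(p, "w") as fh:
            fh.write("nutrient\twild_type_mu\tperturbed_mu\tcall\n")
            for c in omission:
                fh.write(f"{c.item}\t{c.wild_type_mu:.8g}\t{c.perturbed_mu:.8g}\t{c.call}\n")
        artifact(p)
        p = out / "reaction_deletion.tsv"
        with open(p, "w") as fh:
            fh.write("reaction\twild_type_mu\tperturbed_mu\tcall\n")
            for c in deletions:
                fh.write(f"{c.item}\t{c.wild_type_mu:.8g}\t{c.perturbed_mu:.8g}\t{c.call}\n")
        artifact(p)
        p = out / "essential_pathways.json"
        _write_json(p, dict(pathways))
        artifact(p)
        done(
            essential_nutrients=sum(c.essential for c in omission),
            essential_reactions=sum(c.essential for c in deletions),
        )

    # ---- maintenance fit, ATP accounting, sensitivity -------------
    if config.rates_path:
        done = stage("maintenance")
        rates = read_rates_tsv(config.rates_path)
        fit = fit_ngam(model_m, rates)
        p = out / "ngam_fit.json"
        _write_json(
            p,
            {
                "grid": fit.grid,
                "errors": fit.errors,
                "best_ngam": fit.best_ngam,
                "predicted_mu_at_best": fit.predicted_mu_at_best,
                "observed_mu": rates.observed_mu,
            },
        )
        artifact(p)
        done(best_ngam=fit.best_ngam)

        done = stage("sensitivity")
        exchange_ids = [r.id for r in model_m.exchanges]
        records = scaled_reduced_costs(sol, exchange_ids) if sol.mu > 0 else []
        p = out / "sensitivity.tsv"
        with open(p, "w") as fh:
            fh.write("reaction\tdirection\treduced_cost\tflux_magnitude\tscaled_reduced_cost\n")
            for rec in records:
                fh.write(
                    f"{rec.reaction_id}\t{rec.direction}\t{rec.w:.8g}\t"
                    f"{rec.q:.8g}\t{rec.W:.8g}\n"
                )
        artifact(p)
        done(n_records=len(records))

        if config.atp_roles is not None:
            done = stage("atp_accounting")
            acct = atp_accounting(sol, config.atp_roles)
            p = out / "atp_accounting.json"
            _write_json(p, dataclasses.asdict(acct))
            artifact(p)
            done(network_rate=acct.network_rate)

    # ---- sampling --------------------------------------------------
    if config.sample:
        done = stage("sampling")
        cfg = dataclasses.replace(config.sampler, seed=config.seed)
        samples = hit_and_run_sample(model_m, cfg)
        top, tally = top_variable_reactions(samples, model_m, k=min(50, len(model_m.reactions)))
        p = out / "sampling_summary.json"
        _write_json(
            p,
            {
                "feasibility_report": samples.feasibility_report,
                "top_variable_reactions": top,
                "pathway_tally": dict(tally),
                "n_points": cfg.n_points,
                "thinning_steps": cfg.thinning_steps,
                "seed": cfg.seed,
            },
        )
        artifact(p)
        done(n_points=cfg.n_points)

    manifest["wall_clock_s"] = round(
        sum(s.get("seconds", 0.0) for s in manifest["stages"].values()), 3
    )
    _write_json(out / "manifest.json", manifest)
    return manifest
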