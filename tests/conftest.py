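"""Shared fixtures: small hand-built models, the generated toy network,
and an independent brute-force LP oracle (vertex enumeration)."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from oenoflux.model import (
    Compartment,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
)
from oenoflux.synthetic import (
    ToyNetworkConfig,
    default_medium,
    make_toy_lab_model,
)


def build_chain_model(uptake_lb: float = -10.0, uptake_ub: float = 0.0) -> MetabolicModel:
    """EX_A -> transport -> drain: a single-path bottleneck network."""
    m = MetabolicModel(id="chain")
    m.add_metabolite(Metabolite("A_e", compartment=Compartment.EXTRACELLULAR))
    m.add_metabolite(Metabolite("B_c", compartment=Compartment.INTRACELLULAR))
    m.add_reaction(
        Reaction("EX_A", stoichiometry={"A_e": -1}, lower_bound=uptake_lb,
                 upper_bound=uptake_ub, kind=ReactionKind.EXCHANGE)
    )
    m.add_reaction(
        Reaction("R1", stoichiometry={"A_e": -1, "B_c": 1}, lower_bound=0,
                 upper_bound=1000, kind=ReactionKind.TRANSPORT)
    )
    m.add_reaction(
        Reaction("BIO", stoichiometry={"B_c": -1}, lower_bound=0, upper_bound=1000,
                 kind=ReactionKind.BIOMASS)
    )
    m.objective_id = "BIO"
    m.validate()
    return m


def brute_force_lp_max(model: MetabolicModel, objective: str) -> float:
    """Vertex enumeration oracle for max v_obj s.t. S v = 0, l <= v <= u.

    Enumerates all candidate basic feasible solutions by pinning every
    subset of (n - rank S) variables to a bound and solving the square
    remainder; independent of the simplex path used by the package.
    """
    from oenoflux.model import build_stoichiometric_matrix

    S = build_stoichiometric_matrix(model).entries.toarray()
    n = S.shape[1]
    lo = np.array([r.lower_bound for r in model.reactions], float)
    hi = np.array([r.upper_bound for r in model.reactions], float)
    obj_col = [r.id for r in model.reactions].index(objective)
    rank = np.linalg.matrix_rank(S)
    d = n - rank
    best = -np.inf
    for nonbasic in itertools.combinations(range(n), d):
        basic = [j for j in range(n) if j not in nonbasic]
        B = S[:, basic]
        if np.linalg.matrix_rank(B) < len(basic):
            continue
        for corner in itertools.product(*[(lo[j], hi[j]) for j in nonbasic]):
            rhs = -S[:, list(nonbasic)] @ np.array(corner)
            vB, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v = np.empty(n)
            v[list(nonbasic)] = corner
            v[basic] = vB
            if np.abs(S @ v).max() > 1e-8:
                continue
            if (v < lo - 1e-8).any() or (v > hi + 1e-8).any():
                continue
            best = max(best, v[obj_col])
    return best


@pytest.fixture(scope="session")
def toy():
    """Default toy LAB network with its ground truth."""
    model, truth = make_toy_lab_model()
    return model, truth


@pytest.fixture(scope="session")
def toy_with_orphans():
    cfg = ToyNetworkConfig(planted_orphan_metabolites=3)
    model, truth = make_toy_lab_model(cfg)
    return model, truth, cfg


@pytest.fixture(scope="session")
def toy_medium():
    return default_medium()


@pytest.fixture()
def chain_model():
    return build_chain_model()
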