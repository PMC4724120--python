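"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's LP path:
``brute_force_optimum`` enumerates the basic feasible solutions (vertices) of
small flux polytopes directly, and ``to_cobra`` rebuilds a model in cobrapy
so its solver can be used as an independent reference.
"""

import itertools
import math

import numpy as np
import pytest

from commfba import (
    ExchangePolicy,
    Metabolite,
    Reaction,
    StoichiometricModel,
    assemble,
)
from commfba.toys import ToySpec, ToySpeciesParams, make_toy_pair


# ---------------------------------------------------------------------------
# independent LP oracle: vertex enumeration
# ---------------------------------------------------------------------------

def brute_force_optimum(model, objective, sense="max"):
    """Optimum of c^T r over {N r = 0, lb <= r <= ub} by enumerating vertices.

    At a vertex, n - rank(N) fluxes sit at a bound and the rest are uniquely
    determined by the balance equations.  Requires finite bounds; intended
    for fixtures with at most ~8 reactions.
    """
    N, _, cols = model.stoichiometric_matrix()
    n = len(cols)
    c = np.zeros(n)
    if isinstance(objective, str):
        objective = {objective: 1.0}
    index = {rid: j for j, rid in enumerate(cols)}
    for rid, w in objective.items():
        c[index[rid]] = w
    lb = np.array([model.reactions[rid].lb for rid in cols])
    ub = np.array([model.reactions[rid].ub for rid in cols])
    assert np.all(np.isfinite(lb)) and np.all(np.isfinite(ub)), "finite bounds only"

    rank = np.linalg.matrix_rank(N) if N.size else 0
    k = n - rank
    best = None
    for fixed_set in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed_set]
        N_free = N[:, free] if N.size else np.zeros((0, len(free)))
        if len(free) and np.linalg.matrix_rank(N_free) < len(free):
            continue
        for values in itertools.product(*[(lb[j], ub[j]) for j in fixed_set]):
            x = np.empty(n)
            for j, v in zip(fixed_set, values):
                x[j] = v
            if len(free):
                rhs = -N[:, list(fixed_set)] @ np.array(values) if N.size else 0
                sol, *_ = np.linalg.lstsq(N_free, rhs, rcond=None)
                if np.max(np.abs(N_free @ sol - rhs), initial=0) > 1e-8:
                    continue
                x[free] = sol
            if np.any(x < lb - 1e-9) or np.any(x > ub + 1e-9):
                continue
            val = float(c @ x)
            if best is None:
                best = val
            elif sense == "max":
                best = max(best, val)
            else:
                best = min(best, val)
    return best


def to_cobra(model):
    """Rebuild a StoichiometricModel in cobrapy (independent solver route)."""
    import cobra

    cb = cobra.Model(model.id)
    mets = {}
    for met in model.metabolites.values():
        m = cobra.Metabolite(met.id, compartment=met.compartment or "c")
        mets[met.id] = m
    for rxn in model.reactions.values():
        r = cobra.Reaction(rxn.id)
        r.lower_bound = rxn.lb if math.isfinite(rxn.lb) else -1e6
        r.upper_bound = rxn.ub if math.isfinite(rxn.ub) else 1e6
        cb.add_reactions([r])
        r.add_metabolites(
            {mets[mid]: coef for mid, coef in rxn.stoichiometry.items()
             if not model.metabolites[mid].is_boundary}
        )
    return cb


def random_bounded_network(rng, n_reactions=6, n_metabolites=3):
    """Random fully bounded flux network; the zero vector is always feasible."""
    model = StoichiometricModel("random")
    for i in range(n_metabolites):
        model.add_metabolite(Metabolite(f"m{i}"))
    for j in range(n_reactions):
        stoich = {}
        for i in rng.choice(n_metabolites, size=rng.integers(1, 3), replace=False):
            stoich[f"m{int(i)}"] = float(rng.choice([-2, -1, 1, 2]))
        reversible = bool(rng.random() < 0.5)
        ub = float(rng.uniform(1, 10))
        lb = -float(rng.uniform(1, 10)) if reversible else 0.0
        model.add_reaction(
            Reaction(f"r{j}", stoich, lb=lb, ub=ub, reversible=reversible)
        )
    return model


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def chain_model():
    """Forced linear pathway: uptake (ub 10) -> A -> biomass at 0.05 gDW/mmol."""
    m = StoichiometricModel("chain")
    m.add_metabolite(Metabolite("S", compartment="environment", is_boundary=True))
    m.add_metabolite(Metabolite("A"))
    m.add_reaction(Reaction("uptake", {"S": -1.0, "A": 1.0}, lb=0.0, ub=10.0))
    m.add_reaction(Reaction("biomass", {"A": -20.0}, lb=0.0, ub=math.inf))
    m.add_reaction(Reaction("blocked", {"A": -1.0}, lb=0.0, ub=0.0))
    m.objective = {"biomass": 1.0}
    return m


@pytest.fixture
def default_pair():
    """No-waste toy pair: unique balanced point F_A = 5/7, mu_C = 0.30."""
    return make_toy_pair()


@pytest.fixture
def waste_spec():
    base = ToySpec()
    return ToySpec(
        producer=ToySpeciesParams(
            base.producer.yield_gdw_per_mmol, base.producer.uptake_cap, waste=True
        ),
        consumer=ToySpeciesParams(
            base.consumer.yield_gdw_per_mmol, base.consumer.uptake_cap, waste=True
        ),
    )


@pytest.fixture
def waste_pair(waste_spec):
    """Toy pair where both species may waste ATP: off-balance compositions
    are feasible with OptDeg < 1."""
    return make_toy_pair(waste_spec)


@pytest.fixture
def waste_community(waste_pair):
    producer, consumer, policy = waste_pair
    return assemble([producer, consumer], policy)
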