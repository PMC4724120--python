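"""Hierarchical community optimization and the optimality degree.

The primary objective maximizes the community growth rate ``mu_C`` at a given
composition ``F``.  Because the optimum typically admits many flux
distributions — including "altruistic" ones where a species wastes substrate
to keep the community balanced — a secondary LP minimizes

    z = sum over (species i, substrate S_i) of  r_Si * Ymax_{Xi/Si}(mu_C)

the substrate uptake rates weighted by the species' maximum biomass yield on
that substrate at the (fixed) community growth rate.  ``z_opt`` is the
minimal total biomass synthesis rate the community could achieve if every
species converted its substrate at maximum yield; the optimality degree

    OptDeg = mu_C / z_opt

equals 1 when every species grows at maximum biomass yield, is below 1 when
at least one species wastes substrate, and can exceed 1 only when a species
co-utilizes several substrates whose combination outperforms the sum of the
single-substrate yields.

Yields are growth-rate dependent whenever ATP maintenance is nonzero, so the
yield table is recomputed (and cached) per community growth rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

from . import core
from .community import (
    CommunityComposition,
    CommunityModel,
    SpeciesSpec,
    split_pool_transports,
)

#: |OptDeg - 1| below this is reported as exactly optimal.
OPTDEG_TOL = 1e-4

_MU_KEY_DIGITS = 9


@dataclass
class HierarchicalResult:
    """Outcome of the two-level optimization at one composition."""

    mu_c_opt: float
    z_opt: float
    optdeg: float
    fluxes: Optional[core.FluxDistribution]
    substrate_uptakes: Dict[Tuple[str, str], float]
    feasible: bool
    composition: Optional[CommunityComposition] = None

    @classmethod
    def infeasible(cls, F=None) -> "HierarchicalResult":
        return cls(0.0, math.nan, math.nan, None, {}, False, F)


def max_community_growth(cm: CommunityModel, F) -> float:
    """Maximum community growth rate at composition ``F`` (0 if infeasible)."""
    model = cm.instantiate(F)
    sol = core.fba(model, cm.community_rxn, "max")
    if sol.status != "optimal":
        return 0.0
    return sol.objective_value


def species_yield_at(
    spec: SpeciesSpec, substrate: str, mu_c: float
) -> Optional[float]:
    """Maximum biomass yield of one species on one substrate at growth ``mu_c``.

    Computed in the single-species model: all other configured substrates
    blocked, ATP maintenance active, growth fixed to ``mu_c``; the yield is
    ``mu_c`` divided by the minimal substrate uptake.  Returns ``None`` when
    the substrate cannot support that growth rate (its summand is omitted
    from the secondary objective).
    """
    model, uptakes, _ = split_pool_transports(spec.model, spec.substrates)
    for rid, cap in spec.rate_caps:
        if rid in model.reactions:
            model.reactions[rid].ub = min(model.reactions[rid].ub, cap)
    if spec.maintenance_rxn is not None:
        model.reactions[spec.maintenance_rxn].lb = spec.atp_maintenance
    for other in spec.substrates:
        if other == substrate:
            continue
        for rid in uptakes.get(other, []):
            model.reactions[rid].lb = 0.0
            model.reactions[rid].ub = 0.0
    cols = uptakes.get(substrate, [])
    if not cols:
        return None

    growth = model.reactions[spec.biomass_rxn]
    growth.lb = mu_c
    growth.ub = mu_c
    objective = {rid: 1.0 for rid in cols}
    try:
        min_uptake = core.flux_extremum(model, objective, sense="min")
    except core.InfeasibleError:
        return None
    if min_uptake <= core.FEASIBILITY_TOL:
        if mu_c <= core.FEASIBILITY_TOL:
            # zero growth, zero maintenance: the growth-independent true yield
            growth.lb = 0.0
            growth.ub = math.inf
            try:
                return core.fractional_extremum(
                    model, {spec.biomass_rxn: 1.0}, objective, "max"
                )
            except (core.InfeasibleError, core.UnboundedError):
                return None
        return None
    return mu_c / min_uptake


class YieldTable:
    """Per-(species, substrate) maximum yields at a stated growth rate."""

    def __init__(self, mu_c: float, entries: Dict[Tuple[str, str], Optional[float]]):
        self.mu_c = mu_c
        self.entries = entries

    def __getitem__(self, key):
        return self.entries[key]

    def items(self):
        return self.entries.items()


def yield_table(
    cm: CommunityModel,
    mu_c: float,
    cache: Optional[Dict] = None,
) -> YieldTable:
    """Compute (with optional cross-call caching) the yield table at ``mu_c``."""
    entries: Dict[Tuple[str, str], Optional[float]] = {}
    mu_key = round(mu_c, _MU_KEY_DIGITS)
    for spec in cm.species:
        for sub in spec.substrates:
            key = (spec.species_id, sub, mu_key)
            if cache is not None and key in cache:
                y = cache[key]
            else:
                y = species_yield_at(spec, sub, mu_c)
                if cache is not None:
                    cache[key] = y
            entries[(spec.species_id, sub)] = y
    return YieldTable(mu_c, entries)


def min_weighted_substrate(
    cm: CommunityModel,
    F,
    mu_c: float,
    yields: YieldTable,
) -> Tuple[float, core.FluxDistribution]:
    """Secondary LP: minimize yield-weighted substrate consumption at fixed
    ``mu_C``.  Returns ``(z_opt, fluxes)``; raises
    :class:`~commfba.core.InfeasibleError` if ``mu_c`` is not attainable."""
    if not isinstance(F, CommunityComposition):
        F = cm.composition(F)
    model = cm.instantiate(F)
    growth = model.reactions[cm.community_rxn]
    growth.lb = mu_c
    growth.ub = mu_c

    frac = dict(zip(cm.species_ids, F))
    objective: Dict[str, float] = {}
    for (sid, sub), y in yields.items():
        if y is None or frac[sid] == 0.0:
            continue
        for rid in cm.uptake_reactions.get((sid, sub), []):
            objective[rid] = objective.get(rid, 0.0) + y
    if not objective:
        raise core.InfeasibleError("no substrate summands (all yields unavailable)")
    sol = core.fba(model, objective, "min")
    if sol.status != "optimal":
        raise core.InfeasibleError(
            f"community growth rate {mu_c} infeasible at composition {tuple(F)}"
        )
    return sol.objective_value, sol


def optdeg(
    cm: CommunityModel,
    F,
    mu_c: Union[str, float] = "max",
    cache: Optional[Dict] = None,
) -> HierarchicalResult:
    """Full hierarchical optimization at composition ``F``.

    With ``mu_c="max"`` the primary LP determines the maximum community
    growth rate first; with a number, biomass-yield optimality is evaluated
    at that fixed growth rate (the chemostat variant).  Infeasible
    compositions are reported via ``feasible=False``, not raised.
    """
    if not isinstance(F, CommunityComposition):
        F = cm.composition(F)
    if mu_c == "max":
        mu = max_community_growth(cm, F)
        if mu <= core.FEASIBILITY_TOL:
            return HierarchicalResult.infeasible(F)
    else:
        mu = float(mu_c)
        if mu <= 0:
            return HierarchicalResult.infeasible(F)

    yields = yield_table(cm, mu, cache)
    try:
        z_opt, sol = min_weighted_substrate(cm, F, mu, yields)
    except core.InfeasibleError:
        return HierarchicalResult.infeasible(F)

    uptakes: Dict[Tuple[str, str], float] = {}
    for (sid, sub), rids in cm.uptake_reactions.items():
        uptakes[(sid, sub)] = sum(sol.fluxes.get(rid, 0.0) for rid in rids)

    od = mu / z_opt if z_opt > 0 else math.nan
    if abs(od - 1.0) <= OPTDEG_TOL:
        od = 1.0
    return HierarchicalResult(mu, z_opt, od, sol, uptakes, True, F)
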