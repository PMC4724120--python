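"""Assembly of single-species models into balanced-growth community models.

Each species model becomes a namespaced compartment (suffix ``_<species_id>``
on every internal metabolite and reaction).  Metabolites listed in the
exchange policy are merged into a shared pool compartment (suffix ``_pool``)
through which species trade.  A species biomass metabolite ``BM_<id>`` is
produced by each species' biomass reaction, and a community growth reaction
consumes ``F_i`` gram of each ``BM_i`` to make one gram of community biomass
``BM_C`` (a boundary metabolite).  Its rate is the community growth rate
``mu_C`` (1/h); the balance on ``BM_i`` then forces every species' biomass
production rate to equal ``F_i * mu_C`` — the balanced-growth condition under
which the composition ``F`` is stationary.

All fluxes in the community model refer to a gram of *community* dry weight,
so species-specific capacities (uptake/production caps, ATP maintenance) must
be multiplied by ``F_i``; that scaling is applied when a template is
instantiated at a concrete composition.

Every species transport touching a pool metabolite is split into two
irreversible reactions (uptake >= 0, export >= 0) so that substrate uptake
fluxes are sign-safe for the yield-weighted secondary objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .core import (
    Metabolite,
    ModelConsistencyError,
    Reaction,
    StoichiometricModel,
)

SIMPLEX_TOL = 1e-12

CLOSED = "closed"
ACCUMULATING = "accumulating"
MEDIUM = "medium"
_POLICIES = (CLOSED, ACCUMULATING, MEDIUM)


class AssemblyError(ValueError):
    """A species/policy combination cannot be assembled into a community."""


@dataclass
class SpeciesSpec:
    """One community member: its model plus community-facing parameters.

    Parameters
    ----------
    substrates:
        Pool metabolite ids whose uptake by this species enters the
        yield-weighted secondary objective (one summand per substrate used).
    atp_maintenance:
        Non-growth-associated ATP demand, mmol ATP per gDW of this species
        per h, imposed as the lower bound of ``maintenance_rxn``.
    rate_caps:
        ``(reaction_id, cap)`` pairs; each cap (per gDW of this species per
        h) becomes the reaction's upper bound and is F-scaled on assembly.
    """

    model: StoichiometricModel
    species_id: str
    biomass_rxn: str
    substrates: Tuple[str, ...] = ()
    atp_maintenance: float = 0.0
    maintenance_rxn: Optional[str] = None
    rate_caps: Tuple[Tuple[str, float], ...] = ()

    def __post_init__(self):
        if self.biomass_rxn not in self.model.reactions:
            raise AssemblyError(
                f"{self.species_id}: biomass reaction {self.biomass_rxn!r} not in model"
            )
        if self.atp_maintenance < 0:
            raise AssemblyError(f"{self.species_id}: atp_maintenance must be >= 0")
        if self.atp_maintenance > 0 and self.maintenance_rxn is None:
            raise AssemblyError(
                f"{self.species_id}: atp_maintenance > 0 needs a maintenance_rxn"
            )
        for rid, cap in self.rate_caps:
            if rid not in self.model.reactions:
                raise AssemblyError(f"{self.species_id}: capped reaction {rid!r} not in model")
            if cap <= 0:
                raise AssemblyError(f"{self.species_id}: cap for {rid!r} must be > 0")


class CommunityComposition:
    """Biomass fractions ``F_i`` (gDW_i / gDW_C) on the unit simplex."""

    def __init__(self, fractions: Sequence[float]):
        fractions = tuple(float(f) for f in fractions)
        if any(f < -SIMPLEX_TOL or f > 1 + SIMPLEX_TOL for f in fractions):
            raise ValueError(f"fractions must lie in [0, 1]: {fractions}")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1: {fractions}")
        self.fractions = tuple(min(max(f, 0.0), 1.0) for f in fractions)

    def __len__(self):
        return len(self.fractions)

    def __iter__(self):
        return iter(self.fractions)

    def __getitem__(self, i):
        return self.fractions[i]

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"CommunityComposition({self.fractions})"


class ExchangePolicy:
    """Accumulation policy per pool metabolite.

    ``closed`` metabolites have no environment exchange and must be fully
    consumed within the community (e.g. hydrogen and formate in a syntrophic
    acetogen-methanogen community); ``accumulating`` metabolites may be
    exported to the environment (e.g. acetate, CO2, methane); ``medium``
    metabolites may be taken up from the environment (the primary substrate).
    """

    def __init__(self, policies: Mapping[str, str]):
        for met, pol in policies.items():
            if pol not in _POLICIES:
                raise ValueError(f"unknown policy {pol!r} for {met!r}")
        self.policies: Dict[str, str] = dict(policies)

    def __getitem__(self, met):
        return self.policies[met]

    def __contains__(self, met):
        return met in self.policies

    def items(self):
        return self.policies.items()


def pool_id(met_id: str) -> str:
    return f"{met_id}_pool"


def env_uptake_id(met_id: str) -> str:
    return f"EX_{met_id}_medium"


def env_export_id(met_id: str) -> str:
    return f"EX_{met_id}_out"


class CommunityModel:
    """Assembled community template, instantiable at any composition ``F``.

    Attributes of interest:

    ``uptake_reactions``
        Maps ``(species_id, pool_metabolite)`` to the (irreversible) reaction
        ids by which that species consumes the metabolite from the pool.
    ``scaled_lower`` / ``scaled_upper``
        Registered species-specific bounds (maintenance, rate caps), stored
        per gDW of the species; multiplied by ``F_i`` on instantiation.
    """

    def __init__(self, template: StoichiometricModel, species: List[SpeciesSpec]):
        self.template = template
        self.species = list(species)
        self.species_ids = [s.species_id for s in species]
        self.biomass_rxns: Dict[str, str] = {}
        self.community_rxn = "community_growth"
        self.pool_metabolites: List[str] = []
        self.uptake_reactions: Dict[Tuple[str, str], List[str]] = {}
        self.export_reactions: Dict[Tuple[str, str], List[str]] = {}
        self.env_uptake: Dict[str, str] = {}
        self.env_export: Dict[str, str] = {}
        self.scaled_lower: Dict[Tuple[str, str], float] = {}
        self.scaled_upper: Dict[Tuple[str, str], float] = {}
        self.species_reactions: Dict[str, List[str]] = {}

    @property
    def n_species(self) -> int:
        return len(self.species)

    def composition(self, fractions: Sequence[float]) -> CommunityComposition:
        if len(fractions) != self.n_species:
            raise ValueError(
                f"expected {self.n_species} fractions, got {len(fractions)}"
            )
        return CommunityComposition(fractions)

    def instantiate(self, F) -> StoichiometricModel:
        """Concrete model at composition ``F``: community biomass coefficients
        set to ``F_i``, registered species bounds multiplied by ``F_i``, and
        all reactions of species with ``F_i = 0`` shut off."""
        if not isinstance(F, CommunityComposition):
            F = self.composition(F)
        if len(F) != self.n_species:
            raise ValueError("composition length does not match species count")
        model = self.template.copy()
        frac = dict(zip(self.species_ids, F))

        growth = model.reactions[self.community_rxn]
        for sid in self.species_ids:
            growth.stoichiometry[f"BM_{sid}"] = -frac[sid]

        for (sid, rid), base in self.scaled_lower.items():
            model.reactions[rid].lb = base * frac[sid]
        for (sid, rid), base in self.scaled_upper.items():
            ub = base * frac[sid]
            rxn = model.reactions[rid]
            rxn.ub = ub
            rxn.lb = min(rxn.lb, ub)

        for sid, f in frac.items():
            if f == 0.0:
                for rid in self.species_reactions[sid]:
                    rxn = model.reactions[rid]
                    rxn.lb = 0.0
                    rxn.ub = 0.0
        return model


def _split_touching(
    rxn: Reaction, met_map: Mapping[str, str]
) -> List[Reaction]:
    """Split a reversible reaction touching remapped pool metabolites into
    forward/backward irreversible halves; leave irreversible reactions alone.

    ``met_map`` maps original metabolite ids to pool ids; the returned
    reactions already use pool ids.
    """
    stoich = {met_map.get(m, m): c for m, c in rxn.stoichiometry.items()}
    touches = any(m in met_map for m in rxn.stoichiometry)
    if not touches or rxn.lb >= 0:
        return [
            Reaction(rxn.id, stoich, lb=max(rxn.lb, 0.0) if touches else rxn.lb,
                     ub=rxn.ub, reversible=rxn.lb < 0, name=rxn.name)
        ]
    halves = []
    if rxn.ub > 0:
        halves.append(Reaction(rxn.id, dict(stoich), lb=0.0, ub=rxn.ub, name=rxn.name))
    halves.append(
        Reaction(
            f"{rxn.id}__rev",
            {m: -c for m, c in stoich.items()},
            lb=0.0,
            ub=-rxn.lb,
            name=rxn.name,
        )
    )
    return halves


def split_pool_transports(
    model: StoichiometricModel, met_ids: Sequence[str]
) -> Tuple[StoichiometricModel, Dict[str, List[str]], Dict[str, List[str]]]:
    """Return a copy of ``model`` in which every reaction touching one of
    ``met_ids`` is irreversible, plus maps metabolite -> consuming reaction
    ids (uptakes) and metabolite -> producing reaction ids (exports).

    Used both during community assembly and for single-species yield
    calculations, so uptake fluxes are nonnegative in either context.
    """
    met_map = {m: m for m in met_ids}
    out = StoichiometricModel(model.id)
    for met in model.metabolites.values():
        out.add_metabolite(Metabolite(met.id, met.name, met.compartment, met.is_boundary))
    uptakes: Dict[str, List[str]] = {m: [] for m in met_ids}
    exports: Dict[str, List[str]] = {m: [] for m in met_ids}
    for rxn in model.reactions.values():
        for half in _split_touching(rxn, met_map):
            out.add_reaction(half)
            for m in met_ids:
                coef = half.stoichiometry.get(m, 0.0)
                if coef < 0:
                    uptakes[m].append(half.id)
                elif coef > 0:
                    exports[m].append(half.id)
    out.objective = dict(model.objective)
    return out, uptakes, exports


def assemble(species: Sequence[SpeciesSpec], policy: ExchangePolicy) -> CommunityModel:
    """Merge single-species models into a balanced-growth community template.

    Pool metabolites are the metabolite ids listed in ``policy``; each
    species model must reference them by the same id (they are typically
    boundary metabolites of the single-species models).  Raises
    :class:`AssemblyError` if a declared substrate of a species has no
    transport consuming it.
    """
    ids = [s.species_id for s in species]
    if len(set(ids)) != len(ids):
        raise AssemblyError(f"species ids must be unique: {ids}")

    merged = StoichiometricModel("community_" + "_".join(ids))
    cm = CommunityModel(merged, list(species))

    for met_id, pol in policy.items():
        merged.add_metabolite(Metabolite(pool_id(met_id), met_id, "pool", False))
        cm.pool_metabolites.append(met_id)

    for spec in species:
        sid = spec.species_id
        cm.species_reactions[sid] = []
        met_map = {}
        for met in spec.model.metabolites.values():
            if met.id in policy:
                met_map[met.id] = pool_id(met.id)
            else:
                new_id = f"{met.id}_{sid}"
                met_map[met.id] = new_id
                merged.add_metabolite(
                    Metabolite(new_id, met.name, f"{met.compartment}_{sid}", met.is_boundary)
                )
        pool_map = {m: pool_id(m) for m in policy.policies if m in spec.model.metabolites}

        caps = dict(spec.rate_caps)
        for rxn in spec.model.reactions.values():
            halves = _split_touching(rxn, {m: met_map[m] for m in pool_map})
            for k, half in enumerate(halves):
                base_id = rxn.id if k == 0 else f"{rxn.id}__rev"
                new_id = f"{base_id}_{sid}"
                new_stoich = {
                    (met_map[m] if m in met_map else m): c
                    for m, c in half.stoichiometry.items()
                }
                merged.add_reaction(
                    Reaction(new_id, new_stoich, lb=half.lb, ub=half.ub,
                             reversible=half.lb < 0, name=half.name)
                )
                cm.species_reactions[sid].append(new_id)
                for met_orig in pool_map:
                    coef = new_stoich.get(pool_id(met_orig), 0.0)
                    if coef < 0:
                        cm.uptake_reactions.setdefault((sid, met_orig), []).append(new_id)
                    elif coef > 0:
                        cm.export_reactions.setdefault((sid, met_orig), []).append(new_id)
                if k == 0 and rxn.id in caps:
                    cm.scaled_upper[(sid, new_id)] = caps.pop(rxn.id)
        if caps:
            raise AssemblyError(f"{sid}: capped reactions not found: {sorted(caps)}")

        for sub in spec.substrates:
            if sub not in policy:
                raise AssemblyError(f"{sid}: substrate {sub!r} not in exchange policy")
            if not cm.uptake_reactions.get((sid, sub)):
                raise AssemblyError(f"{sid}: no transport consumes substrate {sub!r}")

        bm_met = f"BM_{sid}"
        merged.add_metabolite(Metabolite(bm_met, f"biomass of {sid}", "biomass", False))
        bm_rxn_id = f"{spec.biomass_rxn}_{sid}"
        merged.reactions[bm_rxn_id].stoichiometry[bm_met] = 1.0
        cm.biomass_rxns[sid] = bm_rxn_id

        if spec.maintenance_rxn is not None:
            maint_id = f"{spec.maintenance_rxn}_{sid}"
            if maint_id not in merged.reactions:
                raise AssemblyError(f"{sid}: maintenance reaction not found")
            cm.scaled_lower[(sid, maint_id)] = spec.atp_maintenance

    for met_id, pol in policy.items():
        consumed = any((s, met_id) in cm.uptake_reactions for s in ids)
        produced = any((s, met_id) in cm.export_reactions for s in ids)
        if not (consumed or produced):
            raise AssemblyError(f"pool metabolite {met_id!r} has no species transport")
        if pol == MEDIUM:
            rid = env_uptake_id(met_id)
            merged.add_reaction(Reaction(rid, {pool_id(met_id): 1.0}, 0.0, math.inf))
            cm.env_uptake[met_id] = rid
        elif pol == ACCUMULATING:
            rid = env_export_id(met_id)
            merged.add_reaction(Reaction(rid, {pool_id(met_id): -1.0}, 0.0, math.inf))
            cm.env_export[met_id] = rid

    merged.add_metabolite(Metabolite("BM_C", "community biomass", "environment", True))
    stoich = {f"BM_{sid}": -1.0 / len(ids) for sid in ids}
    stoich["BM_C"] = 1.0
    merged.add_reaction(Reaction(cm.community_rxn, stoich, 0.0, math.inf))
    merged.objective = {cm.community_rxn: 1.0}
    return cm
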