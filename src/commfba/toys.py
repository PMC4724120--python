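"""Parametric toy cross-feeding communities with closed-form optima.

The toy system is a minimal producer/consumer chain mirroring the structure
of an acetogen-methanogen syntrophy: species A takes up a primary substrate
S (capped per gDW_A), converting each mmol into ``x`` mmol of a cross-fed
metabolite X plus one ATP; species B takes up X (capped per gDW_B),
converting each mmol into one ATP.  Biomass costs ``1/Y0`` ATP per gram, so
``Y0`` is the stoichiometric biomass yield (gDW/mmol substrate).  ATP
maintenance is an explicit hydrolysis reaction with lower bound ``m``
(mmol/gDW/h) so that F-scaling of maintenance is exercised end-to-end.

With maintenance, the apparent yield at growth rate mu is

    Y(mu) = mu * Y0 / (mu + m * Y0)

and balanced growth forces the composition F_A/F_B = Y_A(mu) / (x * Y_B(mu)).
The maximum community growth rate is min_i Y0_i * (cap_i - m_i), set by the
species whose capacity saturates first.

When a species' ``waste`` flag is set, its ATP-hydrolysis reaction is
unbounded above, i.e. the species may run a futile cycle and convert
substrate with suboptimal biomass yield.  Stoichiometrically this is the
same freedom as a direct substrate-to-X waste pathway (each wasted mmol of
substrate still yields ``x`` X), and it is what makes off-balance
compositions feasible (with OptDeg < 1).  Without waste the exact ATP
balance pins the feasible composition uniquely at each growth rate.

Everything here is analytic, so these toys serve as independent ground truth
for the LP-based machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .community import ExchangePolicy, SpeciesSpec
from .core import Metabolite, Reaction, StoichiometricModel

SUBSTRATE = "S"
CROSS_FED = "X"
PRODUCT = "P"


@dataclass
class ToySpeciesParams:
    """One toy species: stoichiometric yield, uptake cap, maintenance, waste."""

    yield_gdw_per_mmol: float
    uptake_cap: float
    maintenance: float = 0.0
    waste: bool = False

    def __post_init__(self):
        if self.yield_gdw_per_mmol <= 0 or self.uptake_cap <= 0:
            raise ValueError("yield and cap must be positive")
        if self.maintenance < 0:
            raise ValueError("maintenance must be nonnegative")

    def apparent_yield(self, mu: float) -> float:
        """Y(mu) = mu*Y0/(mu + m*Y0); the true yield Y0 when mu -> inf or m=0."""
        y0, m = self.yield_gdw_per_mmol, self.maintenance
        if mu <= 0:
            return y0 if m == 0 else 0.0
        return mu * y0 / (mu + m * y0)


@dataclass
class ToySpec:
    """Producer/consumer pair defaults: Y0 = 0.05/0.02 gDW/mmol, caps 10/15
    mmol/gDW/h, one X per S, no maintenance, no waste."""

    producer: ToySpeciesParams = field(
        default_factory=lambda: ToySpeciesParams(0.05, 10.0)
    )
    consumer: ToySpeciesParams = field(
        default_factory=lambda: ToySpeciesParams(0.02, 15.0)
    )
    cross_stoich: float = 1.0    # mmol X per mmol S
    product_stoich: float = 1.0  # mmol end product P per mmol X (consumer)

    def __post_init__(self):
        if self.cross_stoich <= 0:
            raise ValueError("cross_stoich must be positive")


def _toy_species_model(
    species_id: str,
    substrate: str,
    params: ToySpeciesParams,
    products: Tuple[Tuple[str, float], ...] = (),
) -> StoichiometricModel:
    """A 5-reaction species: uptake, catabolism (1 ATP/substrate), product
    export(s), ATP-costed biomass, and explicit ATP maintenance."""
    m = StoichiometricModel(species_id)
    m.add_metabolite(Metabolite(substrate, compartment="environment", is_boundary=True))
    m.add_metabolite(Metabolite(f"{substrate}_c", compartment="c"))
    m.add_metabolite(Metabolite("ATP", compartment="c"))
    cat = {f"{substrate}_c": -1.0, "ATP": 1.0}
    for prod, coef in products:
        m.add_metabolite(Metabolite(prod, compartment="environment", is_boundary=True))
        m.add_metabolite(Metabolite(f"{prod}_c", compartment="c"))
        cat[f"{prod}_c"] = coef
    m.add_reaction(
        Reaction("uptake", {substrate: -1.0, f"{substrate}_c": 1.0},
                 lb=0.0, ub=params.uptake_cap)
    )
    m.add_reaction(Reaction("catabolism", cat, lb=0.0, ub=math.inf))
    for prod, _ in products:
        m.add_reaction(
            Reaction(f"export_{prod}", {f"{prod}_c": -1.0, prod: 1.0},
                     lb=0.0, ub=math.inf)
        )
    m.add_reaction(
        Reaction("biomass", {"ATP": -1.0 / params.yield_gdw_per_mmol},
                 lb=0.0, ub=math.inf)
    )
    m.add_reaction(
        Reaction("maintenance", {"ATP": -1.0},
                 lb=params.maintenance,
                 ub=math.inf if params.waste else params.maintenance)
    )
    m.objective = {"biomass": 1.0}
    return m


def _species_spec(model, sid, substrate, params) -> SpeciesSpec:
    caps = [("uptake", params.uptake_cap)]
    if not params.waste:
        # exact ATP balance: scale the maintenance ceiling with F_i too
        caps.append(("maintenance", max(params.maintenance, 0.0)))
    caps = [(rid, cap) for rid, cap in caps if cap > 0]
    return SpeciesSpec(
        model=model,
        species_id=sid,
        biomass_rxn="biomass",
        substrates=(substrate,),
        atp_maintenance=params.maintenance,
        maintenance_rxn="maintenance",
        rate_caps=tuple(caps),
    )


def make_toy_pair(
    spec: Optional[ToySpec] = None,
) -> Tuple[SpeciesSpec, SpeciesSpec, ExchangePolicy]:
    """Producer/consumer pair plus the exchange policy (S medium, X closed)."""
    spec = spec or ToySpec()
    producer_model = _toy_species_model(
        "producer", SUBSTRATE, spec.producer, ((CROSS_FED, spec.cross_stoich),)
    )
    consumer_model = _toy_species_model(
        "consumer", CROSS_FED, spec.consumer, ((PRODUCT, spec.product_stoich),)
    )
    producer = _species_spec(producer_model, "A", SUBSTRATE, spec.producer)
    consumer = _species_spec(consumer_model, "B", CROSS_FED, spec.consumer)
    policy = ExchangePolicy(
        {SUBSTRATE: "medium", CROSS_FED: "closed", PRODUCT: "accumulating"}
    )
    return producer, consumer, policy


def make_competition_trio(
    spec: Optional[ToySpec] = None,
) -> Tuple[List[SpeciesSpec], ExchangePolicy]:
    """Producer plus two identical consumers competing for X: the optimal
    composition is a line segment (the consumers are exchangeable)."""
    spec = spec or ToySpec()
    producer_model = _toy_species_model(
        "producer", SUBSTRATE, spec.producer, ((CROSS_FED, spec.cross_stoich),)
    )
    producer = _species_spec(producer_model, "A", SUBSTRATE, spec.producer)
    consumers = []
    for sid in ("B1", "B2"):
        model = _toy_species_model(
            f"consumer_{sid}", CROSS_FED, spec.consumer,
            ((PRODUCT, spec.product_stoich),)
        )
        consumers.append(_species_spec(model, sid, CROSS_FED, spec.consumer))
    policy = ExchangePolicy(
        {SUBSTRATE: "medium", CROSS_FED: "closed", PRODUCT: "accumulating"}
    )
    return [producer, *consumers], policy


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------

def oracle_max_growth(spec: ToySpec) -> float:
    """mu_C* = min_i Y0_i (cap_i - m_i): the first capacity to saturate."""
    mu_a = spec.producer.yield_gdw_per_mmol * (
        spec.producer.uptake_cap - spec.producer.maintenance
    )
    mu_b = spec.consumer.yield_gdw_per_mmol * (
        spec.consumer.uptake_cap - spec.consumer.maintenance
    )
    return min(mu_a, mu_b)


def oracle_composition(spec: ToySpec, mu: Optional[float] = None) -> float:
    """Producer fraction F_A* at which both species grow at maximal yield.

    Balanced growth with exact ATP accounting gives
    ``F_A / F_B = Y_A(mu) / (x * Y_B(mu))``; without maintenance this is
    growth-rate independent."""
    if mu is None:
        mu = oracle_max_growth(spec)
    y_a = spec.producer.apparent_yield(mu)
    y_b = spec.consumer.apparent_yield(mu)
    x = spec.cross_stoich
    return y_a / (y_a + x * y_b)


def _atp_demand(params: ToySpeciesParams, mu: float) -> float:
    """ATP needed per gDW of the species per h at growth mu."""
    return mu / params.yield_gdw_per_mmol + params.maintenance


def oracle_optdeg(spec: ToySpec, f_a: float, mu: float) -> float:
    """OptDeg at composition (f_a, 1-f_a) and growth rate mu; NaN if the
    point is infeasible (caps exceeded, or equality impossible without the
    waste pathway)."""
    f_b = 1.0 - f_a
    x = spec.cross_stoich
    if mu <= 0:
        return math.nan
    demand_a = f_a * _atp_demand(spec.producer, mu)        # = required r_S
    demand_b = f_b * _atp_demand(spec.consumer, mu) / x    # r_S needed by B
    r_s = max(demand_a, demand_b)
    if r_s > min(spec.producer.uptake_cap * f_a,
                 spec.consumer.uptake_cap * f_b / x) + 1e-12:
        return math.nan
    if r_s > demand_a + 1e-12 and not spec.producer.waste:
        return math.nan
    if r_s > demand_b + 1e-12 and not spec.consumer.waste:
        return math.nan
    z = r_s * (spec.producer.apparent_yield(mu)
               + x * spec.consumer.apparent_yield(mu))
    return mu / z


def oracle_max_growth_at(spec: ToySpec, f_a: float) -> float:
    """Maximum community growth rate at a fixed composition, for toys where
    both species carry the waste pathway (off-balance points then stay
    feasible).  The binding constraint is the smaller of the two capacity
    limits on the shared substrate flux."""
    if not (spec.producer.waste and spec.consumer.waste):
        raise ValueError("per-composition max growth oracle needs waste enabled")
    f_b = 1.0 - f_a
    if f_a <= 0.0 or f_b <= 0.0:
        return 0.0
    x = spec.cross_stoich
    cap = min(spec.producer.uptake_cap * f_a, spec.consumer.uptake_cap * f_b / x)
    mu_a = spec.producer.yield_gdw_per_mmol * (cap / f_a - spec.producer.maintenance)
    mu_b = spec.consumer.yield_gdw_per_mmol * (cap * x / f_b - spec.consumer.maintenance)
    return max(0.0, min(mu_a, mu_b))


def oracle_balanced_optimum(spec: ToySpec) -> Tuple[float, float]:
    """(F_A*, mu_C*): the yield-balanced composition at the maximum
    community growth rate.  For the default spec: (5/7, 0.30)."""
    mu = oracle_max_growth(spec)
    return oracle_composition(spec, mu), mu


def sample_toy_spec(rng: np.random.Generator, with_maintenance: bool = False) -> ToySpec:
    """Random toy spec with log-uniform parameters spanning one decade.

    Both species get the waste pathway so that off-balance compositions are
    feasible (OptDeg < 1) and the scan landscape is informative.
    """
    def logu(lo, hi):
        return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))

    producer = ToySpeciesParams(
        yield_gdw_per_mmol=logu(0.02, 0.2),
        uptake_cap=logu(5.0, 50.0),
        maintenance=logu(0.5, 5.0) if with_maintenance else 0.0,
        waste=True,
    )
    consumer = ToySpeciesParams(
        yield_gdw_per_mmol=logu(0.01, 0.1),
        uptake_cap=logu(5.0, 50.0),
        maintenance=logu(0.5, 5.0) if with_maintenance else 0.0,
        waste=True,
    )
    return ToySpec(producer=producer, consumer=consumer,
                   cross_stoich=logu(0.5, 5.0))


def oracle_min_product_rate(spec: ToySpec, f_a: float, mu: float) -> float:
    """Minimum end-product export rate at (composition, growth rate): waste
    minimized, so the shared flux is pinned by the larger ATP demand."""
    f_b = 1.0 - f_a
    r_s = max(f_a * _atp_demand(spec.producer, mu),
              f_b * _atp_demand(spec.consumer, mu) / spec.cross_stoich)
    return spec.product_stoich * spec.cross_stoich * r_s
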