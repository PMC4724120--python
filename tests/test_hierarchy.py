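"""Hierarchical optimization: growth maxima, growth-dependent yields, OptDeg."""

import math

import numpy as np
import pytest

from commfba import (
    assemble,
    max_community_growth,
    min_weighted_substrate,
    optdeg,
    species_yield_at,
    yield_table,
)
from commfba.toys import (
    ToySpec,
    ToySpeciesParams,
    make_toy_pair,
    oracle_balanced_optimum,
    oracle_composition,
    oracle_optdeg,
    sample_toy_spec,
)


def _community(spec):
    producer, consumer, policy = make_toy_pair(spec)
    return assemble([producer, consumer], policy)


def test_balanced_point_growth_rate_closed_form(default_pair):
    """At the yield-balanced composition F = (5/7, 2/7) the community grows
    at (Y_A + Y_B) * r_S = 0.30 1/h, set by the consumer's uptake cap."""
    producer, consumer, policy = default_pair
    cm = assemble([producer, consumer], policy)
    assert max_community_growth(cm, [5 / 7, 2 / 7]) == pytest.approx(0.30, abs=1e-9)
    # off the balanced point, the exact-ATP community cannot grow at all
    assert max_community_growth(cm, [0.5, 0.5]) == pytest.approx(0.0, abs=1e-9)


def test_optdeg_unity_at_balanced_point(default_pair):
    """Where both species grow at maximum yield, z_opt equals mu_C and
    OptDeg is exactly one."""
    producer, consumer, policy = default_pair
    cm = assemble([producer, consumer], policy)
    res = optdeg(cm, [5 / 7, 2 / 7], "max")
    assert res.feasible
    assert res.mu_c_opt == pytest.approx(0.30, abs=1e-9)
    assert res.z_opt == pytest.approx(res.mu_c_opt, rel=1e-6)
    assert res.optdeg == pytest.approx(1.0, abs=1e-6)
    assert res.substrate_uptakes[("A", "S")] == pytest.approx(30 / 7, rel=1e-6)


def test_growth_dependent_yield_formula():
    """With maintenance m and 1 ATP per substrate, the apparent yield obeys
    Y(mu) = mu*Y0/(mu + m*Y0); the LP reproduces the algebra on a mu grid."""
    params = ToySpeciesParams(0.05, 10.0, maintenance=2.0, waste=True)
    producer, _, _ = make_toy_pair(ToySpec(producer=params))
    for mu in np.linspace(0.02, 0.35, 7):
        y_lp = species_yield_at(producer, "S", mu)
        y0, m = params.yield_gdw_per_mmol, params.maintenance
        assert y_lp == pytest.approx(mu * y0 / (mu + m * y0), abs=1e-10)


def test_yield_unavailable_when_growth_unreachable():
    """A growth rate beyond the capacity of the substrate marks the yield
    unavailable instead of erroring."""
    producer, _, _ = make_toy_pair()
    assert species_yield_at(producer, "S", 10.0) is None


def test_optdeg_matches_closed_form_under_forced_waste(waste_spec, waste_community):
    """Off-balance compositions force one species to waste ATP; the LP OptDeg
    equals the hand-derived ratio mu / [r_S (Y_A + x Y_B)]."""
    for f_a in (0.3, 0.5, 0.65, 0.8, 0.9):
        res = optdeg(waste_community, [f_a, 1 - f_a], "max")
        assert res.feasible
        expected = oracle_optdeg(waste_spec, f_a, res.mu_c_opt)
        assert res.optdeg == pytest.approx(expected, abs=2e-4)


def test_optdeg_at_most_one_for_single_substrate_communities():
    """With one substrate per species the community cannot beat the
    single-substrate maximum yields: OptDeg <= 1 (random toys)."""
    rng = np.random.default_rng(7)
    for _ in range(15):
        spec = sample_toy_spec(rng, with_maintenance=bool(rng.integers(2)))
        cm = _community(spec)
        for f_a in rng.uniform(0.05, 0.95, size=3):
            res = optdeg(cm, [f_a, 1 - f_a], "max")
            if res.feasible:
                assert res.optdeg <= 1 + 1e-6


def test_optimal_composition_growth_rate_independent_without_maintenance(
    waste_spec, waste_community
):
    """At zero maintenance, yields are growth-rate independent, so the
    OptDeg = 1 composition is the same at every fixed community growth rate."""
    f_star = oracle_composition(waste_spec)
    cache = {}
    for mu in (0.03, 0.1, 0.2, 0.29):
        res = optdeg(waste_community, [f_star, 1 - f_star], mu, cache=cache)
        assert res.feasible
        assert res.optdeg == pytest.approx(1.0, abs=1e-6)
        off = optdeg(waste_community, [0.6, 0.4], mu, cache=cache)
        assert off.feasible and off.optdeg < 0.99


def test_optimal_composition_shifts_with_maintenance_at_low_growth():
    """Nonzero, unequal maintenance makes the optimal composition depend on
    the growth rate: the high-maintenance species' apparent yield collapses
    at low mu, so its optimal fraction shrinks there."""
    spec = ToySpec(
        producer=ToySpeciesParams(0.05, 10.0, maintenance=4.0, waste=True),
        consumer=ToySpeciesParams(0.02, 15.0, maintenance=0.5, waste=True),
    )
    cm = _community(spec)
    cache = {}
    for mu in (0.02, 0.1):
        f_star = oracle_composition(spec, mu)
        res = optdeg(cm, [f_star, 1 - f_star], mu, cache=cache)
        assert res.feasible
        assert res.optdeg == pytest.approx(1.0, abs=1e-6)
    assert oracle_composition(spec, 0.02) < oracle_composition(spec, 0.1)


def test_optdeg_invariant_under_common_rescaling(waste_spec):
    """Scaling all capacities and maintenance by lambda while scaling mu_C by
    lambda leaves OptDeg unchanged (homogeneity of the LP)."""
    lam = 3.0
    scaled = ToySpec(
        producer=ToySpeciesParams(
            waste_spec.producer.yield_gdw_per_mmol,
            lam * waste_spec.producer.uptake_cap,
            lam * waste_spec.producer.maintenance,
            waste=True,
        ),
        consumer=ToySpeciesParams(
            waste_spec.consumer.yield_gdw_per_mmol,
            lam * waste_spec.consumer.uptake_cap,
            lam * waste_spec.consumer.maintenance,
            waste=True,
        ),
    )
    cm1 = _community(waste_spec)
    cm2 = _community(scaled)
    for f_a, mu in ((0.5, 0.1), (0.65, 0.2)):
        a = optdeg(cm1, [f_a, 1 - f_a], mu)
        b = optdeg(cm2, [f_a, 1 - f_a], lam * mu)
        assert a.optdeg == pytest.approx(b.optdeg, abs=1e-8)


def test_infeasible_composition_reported_not_raised(waste_community):
    res = optdeg(waste_community, [1.0, 0.0], "max")
    assert not res.feasible
    assert res.mu_c_opt == 0.0
    assert math.isnan(res.optdeg)


def test_z_opt_exceeds_mu_when_waste_is_forced(waste_spec, waste_community):
    """Forcing a composition below the balanced point makes z_opt > mu_C:
    the producer must oxidize extra substrate relative to its biomass."""
    res = optdeg(waste_community, [0.4, 0.6], "max")
    assert res.feasible
    assert res.z_opt > res.mu_c_opt * (1 + 1e-6)
    yields = yield_table(waste_community, res.mu_c_opt)
    z, _ = min_weighted_substrate(waste_community, [0.4, 0.6], res.mu_c_opt, yields)
    assert z == pytest.approx(res.z_opt, rel=1e-9)
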