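"""Community assembly: pooling, F-scaling, balanced-growth identity."""

import math

import numpy as np
import pytest

from commfba import (
    AssemblyError,
    CommunityComposition,
    ExchangePolicy,
    Metabolite,
    Reaction,
    SpeciesSpec,
    StoichiometricModel,
    assemble,
    fba,
    load_sbml,
    max_community_growth,
    write_sbml,
)
from commfba.toys import ToySpec, ToySpeciesParams, make_toy_pair


def test_assembled_structure(default_pair):
    """Two species sharing X yield a pool metabolite, per-species transports,
    and a community biomass reaction over BM_A and BM_B."""
    producer, consumer, policy = default_pair
    cm = assemble([producer, consumer], policy)
    model = cm.template
    assert "X_pool" in model.metabolites
    assert not model.metabolites["X_pool"].is_boundary
    assert model.metabolites["BM_C"].is_boundary
    growth = model.reactions["community_growth"]
    assert set(growth.stoichiometry) == {"BM_A", "BM_B", "BM_C"}
    assert cm.uptake_reactions[("B", "X")] == ["uptake_B"]
    assert cm.export_reactions[("A", "X")] == ["export_X_A"]
    # closed pool metabolite: no environment exchange reactions
    assert "X" not in cm.env_uptake and "X" not in cm.env_export
    assert "S" in cm.env_uptake and "P" in cm.env_export


def test_assembled_model_size_is_predictable(default_pair):
    """Reaction/metabolite counts equal the sum over species plus exchange
    pools, environment exchanges, and the community biomass reaction."""
    producer, consumer, policy = default_pair
    cm = assemble([producer, consumer], policy)
    n_pool = 3  # S, X, P
    n_env_rxns = 2  # S medium uptake, P accumulation
    expected_rxns = (
        len(producer.model.reactions) + len(consumer.model.reactions)
        + n_env_rxns + 1
    )
    expected_mets = (
        (len(producer.model.metabolites) - 2)   # S, X merged into pools
        + (len(consumer.model.metabolites) - 2)  # X, P merged into pools
        + n_pool + 2 + 1                          # pools, BM_A/BM_B, BM_C
    )
    assert len(cm.template.reactions) == expected_rxns
    assert len(cm.template.metabolites) == expected_mets


def test_substrate_without_transport_rejected():
    m = StoichiometricModel("s")
    m.add_metabolite(Metabolite("S", is_boundary=True))
    m.add_metabolite(Metabolite("A"))
    m.add_reaction(Reaction("biomass", {"A": -1.0}, ub=10.0))
    m.add_reaction(Reaction("make", {"A": 1.0}, ub=10.0))
    spec = SpeciesSpec(m, "solo", "biomass", substrates=("S",))
    with pytest.raises(AssemblyError, match="no transport"):
        assemble([spec], ExchangePolicy({"S": "medium"}))


def test_composition_validation():
    with pytest.raises(ValueError):
        CommunityComposition([0.5, 0.6])
    with pytest.raises(ValueError):
        CommunityComposition([1.2, -0.2])
    assert sum(CommunityComposition([0.37, 0.63])) == pytest.approx(1.0, abs=1e-12)


def test_f_scaling_of_caps_and_maintenance():
    """A producer cap of 10 per gDW_i becomes 5 at F=0.5; ATP maintenance
    4.3 at F=0.3 becomes the community-referenced lower bound 1.29."""
    spec = ToySpec(
        producer=ToySpeciesParams(0.05, 10.0, maintenance=4.3, waste=True),
        consumer=ToySpeciesParams(0.02, 15.0, maintenance=0.9, waste=True),
    )
    producer, consumer, policy = make_toy_pair(spec)
    cm = assemble([producer, consumer], policy)

    inst = cm.instantiate([0.5, 0.5])
    assert inst.reactions["uptake_A"].ub == pytest.approx(5.0)

    inst = cm.instantiate([0.3, 0.7])
    assert inst.reactions["maintenance_A"].lb == pytest.approx(1.29)
    assert inst.reactions["maintenance_B"].lb == pytest.approx(0.9 * 0.7)
    # community biomass coefficients carry F
    growth = inst.reactions["community_growth"]
    assert growth.stoichiometry["BM_A"] == pytest.approx(-0.3)
    assert growth.stoichiometry["BM_B"] == pytest.approx(-0.7)


def test_zero_fraction_shuts_species_off(waste_community):
    """F_i = 0 forces all fluxes of that species to zero; the community is
    infeasible when the missing species is essential."""
    inst = waste_community.instantiate([1.0, 0.0])
    for rid in waste_community.species_reactions["B"]:
        assert (inst.reactions[rid].lb, inst.reactions[rid].ub) == (0.0, 0.0)
    assert max_community_growth(waste_community, [1.0, 0.0]) == pytest.approx(0.0)


def test_single_species_community_identity():
    """An n=1 community at F=(1) grows exactly at the single-species rate."""
    producer, _, _ = make_toy_pair()
    policy = ExchangePolicy({"S": "medium", "X": "accumulating"})
    cm = assemble([producer], policy)
    mu_comm = max_community_growth(cm, [1.0])
    mu_single = fba(producer.model, "biomass", "max").objective_value
    assert mu_comm == pytest.approx(mu_single, rel=1e-9)
    assert mu_single == pytest.approx(0.5)


def test_balanced_growth_identity(waste_community):
    """Every feasible flux vector satisfies r_BMi = F_i * mu_C: probe with
    several different LP objectives at a fixed composition."""
    F = [0.6, 0.4]
    inst = waste_community.instantiate(F)
    probes = [
        {"community_growth": 1.0},
        {"uptake_A": 1.0},
        {"maintenance_B": 1.0, "community_growth": 0.3},
    ]
    for objective in probes:
        sol = fba(inst, objective, "max")
        assert sol.status == "optimal"
        mu = sol.fluxes["community_growth"]
        assert sol.fluxes["biomass_A"] == pytest.approx(0.6 * mu, abs=1e-8)
        assert sol.fluxes["biomass_B"] == pytest.approx(0.4 * mu, abs=1e-8)


def test_closed_pool_has_zero_net_environment_flux(waste_community):
    """The cross-fed metabolite is fully consumed within the community:
    species exports equal species uptakes in every sampled solution."""
    inst = waste_community.instantiate([0.6, 0.4])
    sol = fba(inst, "community_growth", "max")
    exported = sum(
        sol.fluxes[rid] * inst.reactions[rid].stoichiometry["X_pool"]
        for rid in waste_community.export_reactions[("A", "X")]
    )
    consumed = sum(
        -sol.fluxes[rid] * inst.reactions[rid].stoichiometry["X_pool"]
        for rid in waste_community.uptake_reactions[("B", "X")]
    )
    assert exported == pytest.approx(consumed, abs=1e-8)
    assert exported > 0


def test_community_model_sbml_round_trip(tmp_path, waste_community):
    """An instantiated community model survives SBML write/read and solves
    to the same maximum growth rate."""
    inst = waste_community.instantiate([0.65, 0.35])
    path = tmp_path / "community.xml"
    write_sbml(inst, path)
    reloaded = load_sbml(path)
    a = fba(inst, "community_growth", "max").objective_value
    b = fba(reloaded, "community_growth", "max").objective_value
    assert a == pytest.approx(b, abs=1e-9)


def test_reversible_pool_transport_is_split():
    """A reversible transport touching a pool metabolite becomes two
    irreversible reactions classified as uptake and export."""
    m = StoichiometricModel("s")
    m.add_metabolite(Metabolite("S", is_boundary=True))
    m.add_metabolite(Metabolite("A"))
    m.add_reaction(
        Reaction("tr", {"S": -1.0, "A": 1.0}, lb=-5.0, ub=10.0, reversible=True)
    )
    m.add_reaction(Reaction("biomass", {"A": -1.0}, ub=math.inf))
    spec = SpeciesSpec(m, "sp", "biomass", substrates=("S",))
    cm = assemble([spec], ExchangePolicy({"S": "medium"}))
    assert cm.uptake_reactions[("sp", "S")] == ["tr_sp"]
    assert cm.export_reactions[("sp", "S")] == ["tr__rev_sp"]
    assert cm.template.reactions["tr_sp"].lb == 0.0
    assert cm.template.reactions["tr__rev_sp"].ub == pytest.approx(5.0)
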