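"""Kinetic rate laws: pH trapezoid, Monod growth, uptake, mass conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import corechemostat as cc
from corechemostat.model_core import (
    CompiledCommunity,
    ConfigurationError,
    GroupSpec,
    PathwaySpec,
    SpeciesEntry,
    StateVector,
    ValidationError,
    growth_rate,
    make_strains,
    metabolite_production,
    ode_rhs,
    ph_limitation,
    strain_rates,
    uptake_rates,
)
from corechemostat.scenarios import _build_strains
from corechemostat.synthetic_data import generate_parameter_sets


def simple_strain(mu_max=0.5, K=0.01, Y=0.333, products=(("acetate", 88.0, 1.0),),
                  corners=(4.0, 5.0, 8.0, 9.0), water_n=0.0):
    entries = {
        "substrate": SpeciesEntry("substitutable", 180.0, 1.0, half_sat=K, yield_=Y),
    }
    if water_n:
        entries["water"] = SpeciesEntry("water", 18.02, water_n)
    for name, m, n in products:
        entries[name] = SpeciesEntry("product", m, n)
    group = GroupSpec("solo", [PathwaySpec("fermentation", mu_max, entries)], corners)
    return make_strains(group, 1, 0.0, seed=0)[0]


# ---------------------------------------------------------------------------
# pH limitation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ph,corners,expected",
    [
        (6.5, (5.0, 6.0, 7.0, 8.0), 1.0),      # optimal plateau
        (4.9, (5.0, 6.0, 7.0, 8.0), 0.0),      # below the lower extreme
        (5.5, (5.0, 6.0, 7.0, 8.0), 0.5),      # midway up the rising edge
        (7.5, (5.0, 6.0, 7.0, 8.0), 0.5),      # midway down the falling edge
        (8.2, (5.0, 6.0, 7.0, 8.0), 0.0),      # above the upper extreme
        (6.0, (5.0, 6.0, 6.0, 8.0), 1.0),      # degenerate plateau c2 == c3
    ],
)
def test_ph_limitation_values(ph, corners, expected):
    assert ph_limitation(ph, corners) == pytest.approx(expected)


def test_ph_limitation_rejects_bad_corners():
    with pytest.raises(ValidationError):
        ph_limitation(6.0, (7.0, 6.0, 5.0, 4.0))
    with pytest.raises(ValidationError):
        ph_limitation(6.0, (5.0, 5.0, 6.0, 7.0))  # c1 == c2


@settings(max_examples=200, deadline=None)
@given(
    ph=st.floats(0.0, 14.0),
    c1=st.floats(2.0, 6.0),
    d1=st.floats(0.1, 2.0),
    d2=st.floats(0.0, 2.0),
    d3=st.floats(0.1, 2.0),
)
def test_ph_limitation_bounded_and_piecewise_monotone(ph, c1, d1, d2, d3):
    corners = (c1, c1 + d1, c1 + d1 + d2, c1 + d1 + d2 + d3)
    f = ph_limitation(ph, corners)
    assert 0.0 <= f <= 1.0
    eps = 1e-4
    up = ph_limitation(min(ph + eps, corners[1]), corners)
    if ph <= corners[1] - eps:
        assert up >= f - 1e-12  # non-decreasing left of the plateau
    dn = ph_limitation(max(ph, corners[2]) + eps, corners)
    if ph >= corners[2]:
        assert dn <= f + 1e-12  # non-increasing right of the plateau


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------


def test_growth_zero_without_substrate():
    strain = simple_strain()
    state = {"substrate": 0.0, "acetate": 0.0}
    _, mu = growth_rate(strain, state, 6.5)
    assert mu == 0.0
    rates = strain_rates(strain, state, 6.5)
    assert rates.uptake == {} and rates.production == {}


def test_growth_half_saturation_and_saturation():
    strain = simple_strain(mu_max=0.5, K=0.01)
    _, mu_half = growth_rate(strain, {"substrate": 0.01, "acetate": 0.0}, 6.5)
    assert mu_half == pytest.approx(0.25, rel=1e-12)
    _, mu_sat = growth_rate(strain, {"substrate": 1e9, "acetate": 0.0}, 6.5)
    assert mu_sat == pytest.approx(0.5, rel=1e-6)


def test_growth_scaled_by_ph_factor():
    strain = simple_strain(mu_max=0.5, K=0.01, corners=(5.0, 6.0, 7.0, 8.0))
    _, mu = growth_rate(strain, {"substrate": 1e9, "acetate": 0.0}, 5.5)
    assert mu == pytest.approx(0.25, rel=1e-6)


def test_essential_resources_combine_by_minimum():
    entries = {
        "a": SpeciesEntry("essential", 100.0, 1.0, half_sat=0.1, yield_=0.5),
        "b": SpeciesEntry("essential", 50.0, 1.0, half_sat=0.1, yield_=0.5),
        "p": SpeciesEntry("product", 60.0, 1.0),
    }
    group = GroupSpec("duo", [PathwaySpec("pw", 1.0, entries)], (4, 5, 8, 9))
    strain = make_strains(group, 1, 0.0)[0]
    # a saturated, b at half-saturation: the minimum term (0.5) limits
    _, mu = growth_rate(strain, {"a": 1e9, "b": 0.1, "p": 0.0}, 6.5)
    assert mu == pytest.approx(0.5, rel=1e-6)


def test_boosting_resource_multiplies_rate_bounded():
    entries = {
        "s": SpeciesEntry("substitutable", 180.0, 1.0, half_sat=0.01, yield_=0.333),
        "b": SpeciesEntry("boosting", 60.0, 1.0, half_sat=0.05),
        "p": SpeciesEntry("product", 60.0, 1.0),
    }
    group = GroupSpec("boosted", [PathwaySpec("pw", 0.4, entries)], (4, 5, 8, 9))
    strain = make_strains(group, 1, 0.0)[0]
    _, mu_absent = growth_rate(strain, {"s": 1e9, "b": 0.0, "p": 0.0}, 6.5)
    _, mu_full = growth_rate(strain, {"s": 1e9, "b": 1e9, "p": 0.0}, 6.5)
    assert mu_absent == pytest.approx(0.4, rel=1e-6)   # absent booster: unboosted
    assert mu_full == pytest.approx(0.6, rel=1e-6)     # saturated booster: x1.5
    assert mu_absent < mu_full


def test_unresolved_species_raises_configuration_error():
    strain = simple_strain()
    with pytest.raises(ConfigurationError):
        growth_rate(strain, {"something_else": 1.0}, 6.5)


# ---------------------------------------------------------------------------
# Uptake and production
# ---------------------------------------------------------------------------


def test_uptake_is_growth_over_yield():
    # mu = 0.1/h at saturation, Y = 0.333 -> U = 0.3003 g/g/h
    strain = simple_strain(mu_max=0.1, Y=0.333)
    uptake, uw = uptake_rates(strain, {"substrate": 1e9, "acetate": 0.0}, 6.5)
    assert uptake["substrate"] == pytest.approx(0.1 / 0.333, rel=1e-6)
    assert uw == 0.0


def test_zero_growth_means_zero_uptake():
    strain = simple_strain()
    uptake, uw = uptake_rates(strain, {"substrate": 0.0, "acetate": 0.0}, 6.5)
    assert uptake == {} and uw == 0.0


def test_equal_substitutable_resources_split_uptake_equally():
    entries = {
        "r1": SpeciesEntry("substitutable", 100.0, 1.0, half_sat=0.02, yield_=0.4),
        "r2": SpeciesEntry("substitutable", 100.0, 1.0, half_sat=0.02, yield_=0.4),
        "p": SpeciesEntry("product", 60.0, 1.0),
    }
    group = GroupSpec("split", [PathwaySpec("pw", 0.6, entries)], (4, 5, 8, 9))
    strain = make_strains(group, 1, 0.0)[0]
    uptake, _ = uptake_rates(strain, {"r1": 0.5, "r2": 0.5, "p": 0.0}, 6.5)
    assert uptake["r1"] == pytest.approx(uptake["r2"], rel=1e-12)


def test_metabolite_production_residual_split_by_stoichiometric_mass():
    # U = mu/Y = 0.3/(1/3) = 0.9; residual = 0.9 - 0.3 = 0.6 split over
    # products with m*n = 120 and 74
    strain = simple_strain(
        mu_max=0.3, Y=1.0 / 3.0,
        products=(("p1", 60.0, 2.0), ("p2", 74.0, 1.0)),
    )
    prod = metabolite_production(strain, {"substrate": 1e9, "p1": 0.0, "p2": 0.0}, 6.5)
    assert prod["p1"] == pytest.approx(0.6 * 120.0 / 194.0, rel=1e-6)
    assert prod["p2"] == pytest.approx(0.6 * 74.0 / 194.0, rel=1e-6)


def test_yield_one_no_water_leaves_nothing_for_products():
    strain = simple_strain(mu_max=0.3, Y=1.0)
    prod = metabolite_production(strain, {"substrate": 1e9, "acetate": 0.0}, 6.5)
    total = sum(prod.values())
    assert total == pytest.approx(0.0, abs=1e-12)


def test_water_uptake_follows_pathway_stoichiometry():
    # water m*n = 36.04 relative to substrate m*n = 180 -> U_w = U * 36.04/180
    strain = simple_strain(mu_max=0.3, Y=0.5, water_n=2.0)
    uptake, uw = uptake_rates(strain, {"substrate": 1e9, "acetate": 0.0}, 6.5)
    assert uw == pytest.approx(uptake["substrate"] * 36.04 / 180.0, rel=1e-9)


@pytest.mark.parametrize("seed", [0, 1])
def test_mass_conservation_randomized(seed):
    """sum_z M_z + mu == sum_i U_i + U_w for random strains/states/pH."""
    rng = np.random.default_rng(seed)
    groups = generate_parameter_sets(10, seed=seed)
    for group in groups:
        strain = make_strains(group, 1, 0.2, seed=seed)[0]
        species = sorted(group.species() - {"water"})
        for _ in range(5):
            state = {s: float(10 ** rng.uniform(-6, 1)) for s in species}
            ph = float(rng.uniform(2.0, 10.0))
            r = strain_rates(strain, state, ph)
            inflow = sum(r.uptake.values()) + r.water_uptake
            assert abs(r.mass_balance_residual()) <= 1e-9 * max(1.0, inflow)


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------


def test_sterile_washin_relaxes_resources_to_inflow():
    strain = simple_strain()
    state = StateVector(microbes={"solo": 0.0},
                        species={"substrate": 1.0, "acetate": 0.0})
    d = ode_rhs(0.0, state, [strain], dilution_rate=0.2,
                inflow_species={"substrate": 5.0}, ph=6.5)
    assert d.microbes["solo"] == 0.0
    assert d.species["substrate"] == pytest.approx(0.2 * (5.0 - 1.0))
    assert d.species["acetate"] == 0.0


def test_washout_condition_gives_negative_biomass_derivative():
    strain = simple_strain(mu_max=0.05)
    state = StateVector(microbes={"solo": 1.0},
                        species={"substrate": 100.0, "acetate": 0.0})
    d = ode_rhs(0.0, state, [strain], dilution_rate=0.2, ph=6.5)
    assert d.microbes["solo"] < 0.0


def test_baseline_model_has_34_state_variables(bioreactor_community):
    scenario = cc.build_scenario("bioreactor")
    strains = _build_strains(scenario, bioreactor_community)
    species = bioreactor_community.tracked_species()
    assert len(strains) == 17 and len(species) == 17
    assert len(strains) + len(species) == 34
    model = CompiledCommunity(strains, species)
    assert model.n_strains + model.n_species == 34


# ---------------------------------------------------------------------------
# Strain generation
# ---------------------------------------------------------------------------


def test_make_strains_zero_variability_is_identity():
    group = generate_parameter_sets(1, seed=5)[0]
    (strain,) = make_strains(group, 1, 0.0, seed=42)
    assert strain.ph_corners == group.ph_corners
    for sp, pp in zip(strain.pathways, group.pathways):
        assert sp.mu_max == pp.mu_max
        for name in pp.entries:
            assert sp.entries[name] == pp.entries[name]


def test_make_strains_determinism_and_count(bioreactor_community):
    strains_a = [s for g in bioreactor_community.groups
                 for s in make_strains(g, 2, 0.1, seed=7)]
    strains_b = [s for g in bioreactor_community.groups
                 for s in make_strains(g, 2, 0.1, seed=7)]
    assert len(strains_a) == 34  # two strains for each of the 17 groups
    for a, b in zip(strains_a, strains_b):
        assert a.ph_corners == b.ph_corners
        assert [p.mu_max for p in a.pathways] == [p.mu_max for p in b.pathways]


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 10_000), variability=st.floats(0.0, 0.9))
def test_make_strains_always_valid(seed, variability):
    group = generate_parameter_sets(1, seed=3)[0]
    for strain in make_strains(group, 3, variability, seed=seed):
        c1, c2, c3, c4 = strain.ph_corners
        assert c1 < c2 <= c3 < c4
        for p in strain.pathways:
            assert p.mu_max > 0
            for e in p.entries.values():
                if e.half_sat is not None:
                    assert e.half_sat > 0
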