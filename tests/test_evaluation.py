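"""Unit conversions, agreement statistics, composition summary, calibration."""

import numpy as np
import pytest
from scipy import stats

import corechemostat as cc
from corechemostat.evaluation import (
    DEFAULT_CELL_MASS_G,
    ObservationSet,
    calibrate_K,
    compare,
    core_summary,
    gl_to_mM,
    gl_to_pseudolog10,
    k_coordinates,
    lm_fit,
    mM_to_gl,
    rmse,
    rmse_percent,
    with_half_sats,
)
from corechemostat.model_core import ValidationError
from corechemostat.synthetic_data import (
    NoiseModel,
    benchmark_observation_times,
    generate_observations,
    table1_fixture,
)


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------


def test_gl_to_mM_acetate():
    assert gl_to_mM(0.0, 60.05) == 0.0
    assert gl_to_mM(1.0, 60.05) == pytest.approx(16.653, abs=1e-3)


def test_mM_gl_round_trip():
    x = np.array([0.0, 0.3, 12.5])
    np.testing.assert_allclose(mM_to_gl(gl_to_mM(x, 74.08), 74.08), x, rtol=1e-12)


def test_gl_to_mM_rejects_nonpositive_molar_mass():
    with pytest.raises(ValidationError):
        gl_to_mM(1.0, 0.0)


def test_pseudolog10_floor_and_powers_of_ten():
    assert gl_to_pseudolog10(0.0) == 0.0                       # 0 g/L -> 0
    assert gl_to_pseudolog10(DEFAULT_CELL_MASS_G) == 0.0       # 1 bacterium/L
    assert gl_to_pseudolog10(DEFAULT_CELL_MASS_G * 1e9) == pytest.approx(9.0)


def test_pseudolog10_rejects_negative():
    with pytest.raises(ValidationError):
        gl_to_pseudolog10(-1.0)


# ---------------------------------------------------------------------------
# RMSE / RMSE% / regression
# ---------------------------------------------------------------------------


def test_rmse_examples():
    assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert rmse([3.0, 4.0], [1.0, 2.0]) == pytest.approx(2.0)  # constant offset
    assert rmse([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == pytest.approx(
        np.sqrt(2.0 / 3.0))


def test_rmse_rejects_length_mismatch():
    with pytest.raises(ValidationError):
        rmse([1.0], [1.0, 2.0])


def test_rmse_matches_brute_force_loop():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(1, 50))
        a, b = rng.normal(size=n), rng.normal(size=n)
        brute = (sum((x - y) ** 2 for x, y in zip(a, b)) / n) ** 0.5
        assert rmse(a, b) == pytest.approx(brute, abs=1e-12)


def test_rmse_percent_examples():
    assert rmse_percent(0.0, [1.0, 2.0]) == 0.0
    assert rmse_percent(1.5, [1.5, 1.5]) == pytest.approx(100.0)
    assert np.isnan(rmse_percent(0.0, [0.0, 0.0]))


def test_rmse_percent_reproduces_published_self_consistent_row():
    # RMSE 0.31 with observation mean 11.13 log10 bacteria/L -> ~2.78-2.79%
    value = rmse_percent(0.31, np.full(10, 11.13))
    assert value == pytest.approx(2.78, abs=0.02)


def test_lm_fit_recovers_exact_lines():
    obs = np.arange(10.0)
    perfect = lm_fit(obs, obs)
    assert perfect.slope == pytest.approx(1.0)
    assert perfect.p_value < 1e-6
    affine = lm_fit(2.0 * obs + 1.0, obs)
    assert affine.slope == pytest.approx(2.0)
    assert affine.intercept == pytest.approx(1.0)


def test_lm_fit_rejects_constant_observed():
    with pytest.raises(ValidationError):
        lm_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


def test_lm_fit_matches_brute_force_ols():
    rng = np.random.default_rng(1)
    for _ in range(10):
        obs = rng.normal(size=15)
        mod = 0.5 * obs + rng.normal(size=15)
        fit = lm_fit(mod, obs)
        x = np.column_stack([np.ones(15), obs])
        beta = np.linalg.solve(x.T @ x, x.T @ mod)
        resid = mod - x @ beta
        s2 = resid @ resid / (15 - 2)
        se = np.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
        t = beta[1] / se
        p = 2.0 * stats.t.sf(abs(t), df=13)
        assert fit.slope == pytest.approx(beta[1], abs=1e-12)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-12)
        assert fit.p_value == pytest.approx(p, abs=1e-12)


def test_lm_fit_null_p_values_are_uniform():
    """Independent modeled/observed pairs give U(0,1) slope p-values."""
    rng = np.random.default_rng(7)
    pvals = [lm_fit(rng.normal(size=20), rng.normal(size=20)).p_value
             for _ in range(1000)]
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# compare()
# ---------------------------------------------------------------------------


def test_compare_round_trip_is_zero(benchmark):
    _, _, sim = benchmark
    obs = generate_observations(
        sim, times=benchmark_observation_times(),
        noise=NoiseModel(abundance_sigma=0.0, scfa_sigma_mM=0.0))
    rep = compare(sim, obs)
    assert np.allclose(rep.table["rmse"], 0.0)
    assert rep.unmatched == []


def test_compare_detects_constant_log10_shift(benchmark):
    _, _, sim = benchmark
    obs = generate_observations(
        sim, times=benchmark_observation_times(),
        noise=NoiseModel(abundance_sigma=0.0, scfa_sigma_mM=0.0))
    obs.genus_log10["fiber_degrader"] = obs.genus_log10["fiber_degrader"] + 1.0
    rep = compare(sim, obs)
    assert rep.row("fiber_degrader")["rmse"] == pytest.approx(1.0, abs=1e-9)


def test_compare_zero_lactate_gives_zero_rmse_and_missing_percent(benchmark):
    _, _, sim = benchmark
    times = benchmark_observation_times()
    obs = ObservationSet(times=times, scfa_mM={"lactate": np.zeros(len(times))})
    # with a detection limit above the modeled lactate level, both series
    # truncate to zero: RMSE 0 and an undefined (missing) RMSE%
    rep = compare(sim, obs, detection_limit_mM=2.0)
    assert rep.row("lactate")["rmse"] == 0.0
    assert np.isnan(rep.row("lactate")["rmse_pct"])


def test_compare_lists_unmatched_variables(benchmark):
    _, _, sim = benchmark
    times = benchmark_observation_times()
    obs = ObservationSet(times=times,
                         genus_log10={"Atopobium": np.full(len(times), 8.0)},
                         scfa_mM={"caproate": np.zeros(len(times)) + 1.0})
    rep = compare(sim, obs)
    assert set(rep.unmatched) == {"Atopobium", "caproate"}


def test_compare_invariant_to_row_order_and_grid_density(benchmark):
    community, scenario, sim = benchmark
    import copy
    dense = sim
    fine_scn = copy.deepcopy(scenario)
    fine_scn.grid_h = 1.0
    fine = cc.simulate(fine_scn, community)
    obs = generate_observations(
        dense, times=benchmark_observation_times(),
        noise=NoiseModel(abundance_sigma=0.0, scfa_sigma_mM=0.0))
    tidy = obs.to_tidy().sample(frac=1.0, random_state=0)
    obs_shuffled = ObservationSet.from_tidy(tidy)
    rep_a = compare(dense, obs)
    rep_b = compare(dense, obs_shuffled)
    a = rep_a.table.set_index("variable")["rmse"]
    b = rep_b.table.set_index("variable")["rmse"]
    np.testing.assert_allclose(a[b.index], b, rtol=1e-12, atol=1e-12)
    rep_c = compare(fine, obs)
    c = rep_c.table.set_index("variable")["rmse"]
    np.testing.assert_allclose(a[c.index], c, rtol=0.05, atol=0.05)


def test_observation_times_must_be_inside_simulation(benchmark):
    _, _, sim = benchmark
    obs = ObservationSet(times=[100.0, 10_000.0],
                         scfa_mM={"lactate": np.zeros(2)})
    with pytest.raises(ValidationError):
        compare(sim, obs)


# ---------------------------------------------------------------------------
# Core-microbiota composition summary
# ---------------------------------------------------------------------------


def test_core_summary_reproduces_published_fractions():
    table = table1_fixture()
    inoculum = core_summary(table[["fecal_inoculum"]])
    assert inoculum["per_sample"]["fecal_inoculum"] == pytest.approx(48.19, abs=0.005)
    reactors = core_summary(table[["reactor_1", "reactor_2", "reactor_3"]])
    assert reactors["mean"] == pytest.approx(49.78, abs=0.005)
    assert reactors["sd"] == pytest.approx(4.5, abs=0.1)


def test_core_summary_zero_core():
    import pandas as pd
    table = pd.DataFrame({"s1": [0.0, 0.0, 100.0]},
                         index=["GenusA", "GenusB", "Others"])
    out = core_summary(table)
    assert out["per_sample"]["s1"] == pytest.approx(0.0)


def test_core_summary_warns_on_missing_genus():
    table = table1_fixture()[["fecal_inoculum"]]
    out = core_summary(table, core_list=list(table.index[:-1]) + ["Atopobium"])
    assert any("Atopobium" in w for w in out["warnings"])


# ---------------------------------------------------------------------------
# Calibration mechanics (recovery experiments live in the acceptance suite)
# ---------------------------------------------------------------------------


def test_calibrate_budget_zero_returns_initial_vector(benchmark):
    community, scenario, sim = benchmark
    obs = generate_observations(
        sim, times=benchmark_observation_times(),
        noise=NoiseModel(abundance_sigma=0.0, scfa_sigma_mM=0.0))
    res = calibrate_K(community, scenario, obs, budget=0, seed=0)
    assert all(v == pytest.approx(0.001) for v in res.k_values.values())
    assert res.n_evaluations == 1


def test_calibrate_respects_bounds_and_improves(benchmark):
    community, scenario, sim = benchmark
    obs = generate_observations(
        sim, times=benchmark_observation_times(),
        noise=NoiseModel(abundance_sigma=0.0, scfa_sigma_mM=0.0))
    res = calibrate_K(community, scenario, obs, bounds=(1e-3, 0.5),
                      budget=12, seed=4)
    for v in res.k_values.values():
        assert 1e-3 <= v <= 0.5
    scores = [s for _, s in res.trace]
    assert all(b <= a + 1e-15 for a, b in zip(scores, scores[1:]))
    assert scores[-1] <= scores[0]


def test_with_half_sats_replaces_only_addressed_coordinates(benchmark):
    community, _, _ = benchmark
    coords = k_coordinates(community)
    assert len(coords) == 3
    new = with_half_sats(community, {coords[0]: 0.42})
    e = new.group(coords[0].group).pathways[0].entries[coords[0].species]
    assert e.half_sat == pytest.approx(0.42)
    untouched = new.group(coords[1].group).pathways[0].entries[coords[1].species]
    orig = community.group(coords[1].group).pathways[0].entries[coords[1].species]
    assert untouched.half_sat == orig.half_sat
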