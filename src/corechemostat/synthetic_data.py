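"""Synthetic observations, random parameter sets, and packaged fixtures.

The wet-lab side of the study (GC-MS metabolite quantification, qPCR/16S
absolute abundances) is emulated here at the level of the derived
quantities the model is compared against: genus pseudo-log10 bacteria/L
and metabolite mM time series on a dense-early/sparse-late sampling
schedule, with multiplicative lognormal abundance noise, additive Gaussian
metabolite noise, and detection-limit truncation.

Also packaged: the published community-composition table (relative
abundances of the core genera in the fecal inoculum, the three bioreactors
at T0, the in-silico community and the meta-analysis core), and a small
three-group cross-feeding "benchmark world" with documented parameters
used as the known truth for calibration-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _fixture_community as _fix
from .evaluation import (
    DEFAULT_CELL_MASS_G,
    DETECTION_LIMIT_BACTERIA,
    DETECTION_LIMIT_MM,
    ObservationSet,
    gl_to_mM,
)
from .model_core import GroupSpec, PathwaySpec, SpeciesEntry, SpeciesInfo, ValidationError
from .parameter_io import Community
from .scenarios import ChemostatScenario, SimulationResult, simulate

__all__ = [
    "DEFAULT_SCHEDULE_H",
    "NoiseModel",
    "table1_fixture",
    "bioreactor_observations",
    "generate_observations",
    "generate_parameter_sets",
    "benchmark_truth",
    "benchmark_observation_times",
]

#: Default sampling schedule (h): 8 h, then days 1, 1.7, 3, 4, 5.5, 10,
#: 15, 20, 25, 30, 35 — dense early, sparse late.
DEFAULT_SCHEDULE_H = np.array(
    [8.0, 24.0, 40.0, 72.0, 96.0, 132.0, 240.0, 360.0, 480.0, 600.0, 720.0, 840.0]
)

_MAIN_SCFA = ["acetate", "propionate", "butyrate", "lactate"]


@dataclass
class NoiseModel:
    """Measurement-noise stand-in for qPCR/16S and GC-MS error.

    ``abundance_sigma`` is the sigma of a multiplicative lognormal factor
    on bacteria/L (0.15 natural-log units ~ 0.065 log10); ``scfa_sigma_mM``
    is additive Gaussian noise on metabolite mM.  Values below the
    detection limits are reported as 0.  Sigma 0 reproduces the truth.
    """

    abundance_sigma: float = 0.15
    scfa_sigma_mM: float = 2.0
    detection_limit_mM: float = DETECTION_LIMIT_MM
    detection_limit_bacteria: float = DETECTION_LIMIT_BACTERIA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.abundance_sigma < 0 or self.scfa_sigma_mM < 0:
            raise ValidationError("noise sigmas must be >= 0")


# ---------------------------------------------------------------------------
# In-paper composition table
# ---------------------------------------------------------------------------

_TABLE1_ROWS = [
    # genus, inoculum, reactor1, reactor2, reactor3, in_silico_cm, h_cm
    ("Prevotella", 22.27, 22.45, 29.48, 19.16, 23.58, 22.86),
    ("Megasphaera", 6.64, 20.07, 9.11, 12.75, 13.20, 0.88),
    ("RC9", 3.82, 2.60, 2.81, 3.24, 2.93, 2.35),
    ("Streptococcus", 5.08, 1.33, 1.41, 2.10, 1.68, 0.78),
    ("Lactobacillus", 1.95, 2.40, 1.17, 1.91, 1.76, 2.93),
    ("Alloprevotella", 2.33, 1.94, 2.06, 1.73, 1.90, 1.76),
    ("Clostridium", 3.44, 0.78, 0.82, 0.96, 0.87, 3.13),
    ("Treponema", 0.61, 0.57, 0.75, 0.80, 0.73, 4.30),
    ("Faecalibacterium", 0.62, 1.01, 0.96, 1.39, 1.15, 1.17),
    ("Succinivibrio", 0.05, 0.05, 0.03, 0.10, 0.07, 3.32),
    ("Blautia", 0.33, 0.20, 0.27, 0.25, 0.24, 2.15),
    ("Phascolarctobacterium", 0.29, 0.61, 0.50, 0.50, 0.53, 0.98),
    ("Ruminococcus", 0.63, 0.24, 0.29, 0.28, 0.27, 1.17),
    ("Parabacteroides", 0.04, 0.03, 0.04, 0.03, 0.03, 0.98),
    ("Pseudobutyrivibrio", 0.00, 0.00, 0.00, 0.00, np.nan, 0.78),
    ("Bacteroides", 0.00, 0.00, 0.00, 0.00, np.nan, 0.78),
    ("Escherichia", 0.01, 0.00, 0.02, 0.01, 0.01, 0.39),
    ("Sarcina", 0.00, 0.00, 0.00, 0.00, np.nan, 0.29),
    ("Turicibacter", 0.07, 0.03, 0.02, 0.07, 0.04, 0.00),
    ("Others", 51.81, 45.70, 50.25, 54.71, 51.00, 49.00),
]

_TABLE1_COLUMNS = [
    "fecal_inoculum", "reactor_1", "reactor_2", "reactor_3",
    "in_silico_cm", "fecal_h_cm",
]


def table1_fixture() -> pd.DataFrame:
    """Relative abundances (%) of the core genera across samples.

    Rows: 19 genera plus "Others" (Pseudobutyrivibrio, Bacteroides and
    Sarcina are NaN in the in-silico column: absent from all samples,
    hence not modeled).  Columns: fecal inoculum, the three bioreactors at
    T0, the in-silico community, and the meta-analysis fecal core.
    """
    df = pd.DataFrame(
        [r[1:] for r in _TABLE1_ROWS],
        index=pd.Index([r[0] for r in _TABLE1_ROWS], name="genus"),
        columns=_TABLE1_COLUMNS,
    )
    return df.copy()


# ---------------------------------------------------------------------------
# Packaged bioreactor observation fixture (synthetic)
# ---------------------------------------------------------------------------


def bioreactor_observations() -> ObservationSet:
    """Synthetic stand-in for the averaged bioreactor observation series.

    Values are anchored to the published summary statistics (initial and
    steady-state SCFA concentrations, time-averaged genus pseudo-log10
    levels, declining trajectories for the washed-out genera, lactate
    undetected at every sampled time); the curves between anchors are
    interpolations, not measured data.
    """
    times = np.concatenate([[0.0], DEFAULT_SCHEDULE_H])

    scfa = {
        "acetate": np.array([25.88, 62.0, 70.0, 80.62, 55.0, 50.77, 52.0,
                             50.0, 49.0, 48.5, 48.0, 47.8, 47.69]),
        "propionate": np.array([10.68, 40.0, 49.04, 38.72, 44.0, 42.0, 40.0,
                                35.68, 35.0, 34.0, 33.5, 33.0, 32.68]),
        "butyrate": np.array([6.0, 15.0, 21.0, 21.0, 21.0, 28.0, 27.0,
                              27.0, 27.0, 27.0, 26.9, 26.9, 26.9]),
        "lactate": np.zeros(13),
    }

    total = 7.756  # g/L, default initial community biomass
    frac = _fix.IN_SILICO_FRACTIONS

    def log10_initial(name: str) -> float:
        gl = total * frac[name] / 100.0
        return float(np.log10(gl / DEFAULT_CELL_MASS_G))

    genus: dict[str, np.ndarray] = {}
    persist_means = {
        "Prevotella": 12.42,
        "Megasphaera": 11.13,
        "Succinivibrio": 9.86,
        "Blautia": 9.91,
        "Ruminococcus": 10.72,
        "others": 12.50,
    }
    for name, mean in persist_means.items():
        v = np.full(13, mean)
        v[0] = log10_initial(name)
        if name == "Prevotella":  # small early peak before settling
            v[2:5] = mean + 0.25
        genus[name] = v
    washed = [g for g in frac if g not in persist_means]
    for name in washed:
        v0 = log10_initial(name)
        horizon = 840.0 if name == "Phascolarctobacterium" else 360.0
        genus[name] = np.maximum(0.0, v0 * (1.0 - times / horizon))
    return ObservationSet(times=times, genus_log10=genus, scfa_mM=scfa)


# ---------------------------------------------------------------------------
# Observation generation from a simulated truth
# ---------------------------------------------------------------------------


def generate_observations(
    truth: SimulationResult,
    times: Sequence[float] | None = None,
    noise: NoiseModel | None = None,
    metabolites: Sequence[str] | None = None,
    cell_mass: float = DEFAULT_CELL_MASS_G,
) -> ObservationSet:
    """Sample a simulated truth into a noisy, truncated observation set."""
    noise = noise or NoiseModel()
    times = np.asarray(DEFAULT_SCHEDULE_H if times is None else times, dtype=float)
    if len(times) == 0:
        raise ValidationError("empty sampling schedule")
    if times[0] < truth.times[0] - 1e-9 or times[-1] > truth.times[-1] + 1e-9:
        raise ValidationError("sampling times outside the simulated span")
    if metabolites is None:
        metabolites = [m for m in _MAIN_SCFA if m in truth.species.columns]
    rng = np.random.default_rng(noise.seed)

    genus = {}
    for name in truth.groups.columns:
        gl = np.interp(times, truth.times, truth.group_trajectory(name))
        cells = gl / cell_mass
        cells = cells * np.exp(noise.abundance_sigma * rng.standard_normal(len(times)))
        out = np.zeros(len(times))
        above = cells > noise.detection_limit_bacteria
        out[above] = np.log10(cells[above])
        genus[name] = out

    scfa = {}
    for name in metabolites:
        info = truth.community.registry[name]
        gl = np.interp(times, truth.times, truth.species_trajectory(name))
        mM = gl_to_mM(gl, info.molar_mass)
        mM = mM + noise.scfa_sigma_mM * rng.standard_normal(len(times))
        mM = np.maximum(mM, 0.0)
        mM[mM < noise.detection_limit_mM] = 0.0
        scfa[name] = mM
    return ObservationSet(times=times, genus_log10=genus, scfa_mM=scfa)


# ---------------------------------------------------------------------------
# Random parameter sets for property tests
# ---------------------------------------------------------------------------

_RAND_RESOURCES = ["fiber", "sugar", "peptide"]
_RAND_METABOLITES = ["acetate", "propionate", "butyrate", "lactate", "co2", "h2"]
_RAND_MASSES = {
    "fiber": 162.14, "sugar": 180.16, "peptide": 110.0,
    "acetate": 60.05, "propionate": 74.08, "butyrate": 88.11,
    "lactate": 90.08, "co2": 44.01, "h2": 2.016, "water": 18.02,
}


def generate_parameter_sets(n_groups: int, seed: int = 0) -> list[GroupSpec]:
    """Random valid GroupSpecs (for round-trip and conservation tests)."""
    if n_groups < 1:
        raise ValidationError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    groups = []
    for i in range(n_groups):
        pathways = []
        for j in range(int(rng.integers(1, 3))):
            entries: dict[str, SpeciesEntry] = {}
            n_res = int(rng.integers(1, 3))
            resources = list(rng.choice(_RAND_RESOURCES, size=n_res, replace=False))
            rclass = "essential" if rng.random() < 0.3 else "substitutable"
            for sp in resources:
                entries[sp] = SpeciesEntry(
                    rclass, _RAND_MASSES[sp], float(rng.integers(1, 4)),
                    half_sat=float(10 ** rng.uniform(-3, -0.5)),
                    yield_=float(rng.uniform(0.2, 0.6)),
                )
            if rng.random() < 0.5:
                entries["water"] = SpeciesEntry(
                    "water", _RAND_MASSES["water"], float(rng.integers(1, 3)))
            n_prod = int(rng.integers(1, 4))
            prods = list(rng.choice(_RAND_METABOLITES, size=n_prod, replace=False))
            for sp in prods:
                entries[sp] = SpeciesEntry(
                    "product", _RAND_MASSES[sp], float(rng.integers(1, 4)))
            pathways.append(PathwaySpec(
                f"pathway_{j + 1}", float(rng.uniform(0.1, 1.5)), entries))
        c1 = float(rng.uniform(3.0, 5.0))
        c2 = c1 + float(rng.uniform(0.3, 1.5))
        c3 = c2 + float(rng.uniform(0.0, 2.0))
        c4 = c3 + float(rng.uniform(0.3, 1.5))
        groups.append(GroupSpec(f"group_{i + 1}", pathways, (c1, c2, c3, c4)))
    return groups


# ---------------------------------------------------------------------------
# Benchmark truth: a small cross-feeding world with known parameters
# ---------------------------------------------------------------------------

#: True half-saturation constants of the benchmark community (g/L).
BENCHMARK_TRUE_K = {
    ("fiber_degrader", "fiber_fermentation", "fiber"): 0.08,
    ("sugar_fermenter", "sugar_fermentation", "sugar"): 0.15,
    ("lactate_utilizer", "lactate_utilization", "lactate"): 0.05,
}


def _benchmark_community() -> Community:
    registry = {
        "fiber": SpeciesInfo(162.14, "resource"),
        "sugar": SpeciesInfo(180.16, "resource"),
        "acetate": SpeciesInfo(60.05, "metabolite"),
        "propionate": SpeciesInfo(74.08, "metabolite"),
        "butyrate": SpeciesInfo(88.11, "metabolite"),
        "lactate": SpeciesInfo(90.08, "metabolite"),
        "water": SpeciesInfo(18.02, "water"),
    }

    def e(rclass, sp, n=1.0, K=None, Y=None):
        return SpeciesEntry(rclass, _RAND_MASSES.get(sp, registry[sp].molar_mass),
                            n, half_sat=K, yield_=Y)

    fiber_degrader = GroupSpec("fiber_degrader", [
        PathwaySpec("fiber_fermentation", 0.35, {
            "fiber": e("substitutable", "fiber", 1, 0.08, 0.333),
            "water": e("water", "water", 1),
            "acetate": e("product", "acetate", 2),
            "lactate": e("product", "lactate", 2),
        }),
    ], (4.0, 5.0, 8.0, 9.0))
    sugar_fermenter = GroupSpec("sugar_fermenter", [
        PathwaySpec("sugar_fermentation", 0.40, {
            "sugar": e("substitutable", "sugar", 1, 0.15, 0.333),
            "water": e("water", "water", 1),
            "propionate": e("product", "propionate", 2),
            "acetate": e("product", "acetate", 1),
        }),
    ], (4.0, 5.0, 8.0, 9.0))
    lactate_utilizer = GroupSpec("lactate_utilizer", [
        PathwaySpec("lactate_utilization", 0.60, {
            "lactate": e("substitutable", "lactate", 1, 0.05, 0.25),
            "water": e("water", "water", 1),
            "butyrate": e("product", "butyrate", 1),
            "acetate": e("product", "acetate", 1),
        }),
    ], (4.0, 5.0, 8.0, 9.0))
    return Community(
        name="benchmark",
        groups=[fiber_degrader, sugar_fermenter, lactate_utilizer],
        registry=registry,
        initial_fractions={"fiber_degrader": 40.0, "sugar_fermenter": 40.0,
                           "lactate_utilizer": 20.0},
    )


def benchmark_observation_times() -> np.ndarray:
    """Dense-early schedule used for benchmark calibration experiments."""
    return np.concatenate([np.arange(4.0, 49.0, 4.0), np.arange(60.0, 241.0, 20.0)])


def benchmark_truth(seed: int = 0):
    """A 3-group, 2-resource, 4-metabolite world simulated to steady state.

    Cross-feeding chain: a fiber degrader excretes lactate and acetate, a
    sugar fermenter excretes propionate and acetate, and a lactate
    utilizer turns the degrader's lactate into butyrate.  Returns
    (community, scenario, SimulationResult).
    """
    community = _benchmark_community()
    scenario = ChemostatScenario(
        name="benchmark",
        dilution_rate=0.1,
        inflow_resources={"fiber": 5.0, "sugar": 5.0},
        initial_resources={"fiber": 5.0, "sugar": 5.0},
        initial_microbes={"fiber_degrader": 0.05, "sugar_fermenter": 0.05,
                          "lactate_utilizer": 0.02},
        ph=6.5,
        duration_h=240.0,
        grid_h=2.0,
        rtol=1e-7,
        atol=1e-10,
        seed=seed,
        metadata={"community": "benchmark"},
    )
    sim = simulate(scenario, community)
    return community, scenario, sim
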