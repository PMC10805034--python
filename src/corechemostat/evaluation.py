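"""Model-vs-observation scoring, unit conversion, and K calibration.

Model output in g/L is converted to the observation scales: metabolites to
mM via (g/L * 1000) / molar mass, microbial groups to pseudo-log10
bacteria/L assuming a 4.6e-12 g cell, with every value at or below one
bacterium per liter mapped to 0.  Agreement is scored per variable by RMSE,
RMSE as a percentage of the observation mean, and the p-value of an
ordinary least-squares regression of modeled on observed values.

The half-saturation constants are the one parameter class tuned against
data: :func:`calibrate_K` starts every K at the 0.001 g/L convention and
runs a seeded coordinate-wise log-uniform search that minimizes the summed
per-variable RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import ValidationError
from .parameter_io import Community
from .scenarios import ChemostatScenario, SimulationResult, simulate

__all__ = [
    "DEFAULT_CELL_MASS_G",
    "DETECTION_LIMIT_MM",
    "DETECTION_LIMIT_BACTERIA",
    "ObservationSet",
    "ComparisonReport",
    "gl_to_mM",
    "mM_to_gl",
    "gl_to_pseudolog10",
    "rmse",
    "rmse_percent",
    "lm_fit",
    "compare",
    "core_summary",
    "KCoordinate",
    "k_coordinates",
    "with_half_sats",
    "CalibrationResult",
    "calibrate_K",
]

#: Assumed mass of one bacterial cell (g).
DEFAULT_CELL_MASS_G = 4.6e-12
#: Modeled metabolite values below this are reported as undetected (mM).
DETECTION_LIMIT_MM = 0.1
#: Abundance detection floor, bacteria/L.
DETECTION_LIMIT_BACTERIA = 1.0


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------


def gl_to_mM(conc, molar_mass: float):
    """g/L -> mM: (g/L * 1000) / molar mass."""
    if not molar_mass > 0:
        raise ValidationError(f"molar_mass must be > 0, got {molar_mass}")
    return np.asarray(conc, dtype=float) * 1000.0 / molar_mass


def mM_to_gl(conc_mM, molar_mass: float):
    if not molar_mass > 0:
        raise ValidationError(f"molar_mass must be > 0, got {molar_mass}")
    return np.asarray(conc_mM, dtype=float) * molar_mass / 1000.0


def gl_to_pseudolog10(conc, cell_mass: float = DEFAULT_CELL_MASS_G):
    """g/L -> pseudo-log10 bacteria/L (<= 1 bacterium/L maps to 0)."""
    if not cell_mass > 0:
        raise ValidationError(f"cell_mass must be > 0, got {cell_mass}")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValidationError("negative concentration in gl_to_pseudolog10")
    cells = conc / cell_mass
    out = np.zeros_like(cells)
    above = cells > DETECTION_LIMIT_BACTERIA
    out[above] = np.log10(cells[above])
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Observation container
# ---------------------------------------------------------------------------


@dataclass
class ObservationSet:
    """Sampled genus pseudo-log10 and metabolite mM time series."""

    times: np.ndarray
    genus_log10: dict[str, np.ndarray] = field(default_factory=dict)
    scfa_mM: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValidationError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("observation times must be strictly increasing")
        for d in (self.genus_log10, self.scfa_mM):
            for k in d:
                d[k] = np.asarray(d[k], dtype=float)
                if d[k].shape != self.times.shape:
                    raise ValidationError(f"series {k!r} length mismatch")
                if np.any(d[k] < 0):
                    raise ValidationError(f"negative values in series {k!r}")

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for name, v in self.genus_log10.items():
            rows.append(pd.DataFrame({
                "time_h": self.times, "variable": name, "kind": "genus", "value": v}))
        for name, v in self.scfa_mM.items():
            rows.append(pd.DataFrame({
                "time_h": self.times, "variable": name, "kind": "scfa", "value": v}))
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path) -> None:
        self.to_tidy().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "ObservationSet":
        times = np.sort(df["time_h"].unique())
        genus, scfa = {}, {}
        for (name, kind), sub in df.groupby(["variable", "kind"]):
            sub = sub.sort_values("time_h")
            if not np.array_equal(sub["time_h"].to_numpy(), times):
                raise ValidationError(f"series {name!r} not on the common time grid")
            (genus if kind == "genus" else scfa)[name] = sub["value"].to_numpy()
        return cls(times, genus, scfa)

    @classmethod
    def read_tsv(cls, path) -> "ObservationSet":
        return cls.from_tidy(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def rmse(pred, obs) -> float:
    """Root-mean-square error between paired series."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) == 0:
        raise ValidationError("rmse needs two equal-length non-empty 1-D series")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def rmse_percent(rmse_value: float, obs) -> float:
    """RMSE as a percentage of the observation mean (NaN if the mean is 0)."""
    m = float(np.mean(np.asarray(obs, dtype=float)))
    if m == 0.0:
        return float("nan")
    return 100.0 * rmse_value / m


@dataclass(frozen=True)
class LMResult:
    slope: float
    intercept: float
    p_value: float


def lm_fit(modeled, observed) -> LMResult:
    """OLS of modeled on observed; p-value is the slope's two-sided t-test."""
    modeled = np.asarray(modeled, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if modeled.shape != observed.shape or len(modeled) < 3:
        raise ValidationError("lm_fit needs >= 3 paired values")
    if np.ptp(observed) == 0.0:
        raise ValidationError("observed series is constant; regression undefined")
    res = stats.linregress(observed, modeled)
    return LMResult(float(res.slope), float(res.intercept), float(res.pvalue))


# ---------------------------------------------------------------------------
# Model-vs-observation comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Per-variable RMSE / RMSE% / regression p-value table."""

    table: pd.DataFrame  # columns: variable, kind, rmse, rmse_pct, lm_p
    unmatched: list[str] = field(default_factory=list)

    def row(self, variable: str) -> pd.Series:
        sel = self.table[self.table["variable"] == variable]
        if sel.empty:
            raise KeyError(variable)
        return sel.iloc[0]

    def total_rmse(self) -> float:
        return float(self.table["rmse"].sum())


def _truncate_mM(values_mM: np.ndarray, limit: float) -> np.ndarray:
    out = np.array(values_mM, dtype=float)
    out[out < limit] = 0.0
    return out


def compare(
    sim: SimulationResult,
    obs: ObservationSet,
    cell_mass: float = DEFAULT_CELL_MASS_G,
    detection_limit_mM: float = DETECTION_LIMIT_MM,
) -> ComparisonReport:
    """Score a simulation against an observation set, variable by variable.

    The model trajectory is linearly interpolated (in g/L) onto the
    observation times, converted to the observation scale, and subjected to
    the same detection limits as the observations (metabolites below
    ``detection_limit_mM`` mM and abundances below one bacterium per liter
    report as 0).  Variables observed but absent from the simulation are
    listed as unmatched rather than silently dropped.
    """
    t0, t1 = sim.times[0], sim.times[-1]
    if obs.times[0] < t0 - 1e-9 or obs.times[-1] > t1 + 1e-9:
        raise ValidationError("observation times outside the simulated span")

    rows = []
    unmatched = []
    for name, series in obs.genus_log10.items():
        if name not in sim.groups.columns:
            unmatched.append(name)
            continue
        gl = np.interp(obs.times, sim.times, sim.group_trajectory(name))
        pred = gl_to_pseudolog10(gl, cell_mass)
        r = rmse(pred, series)
        rows.append((name, "genus", r, rmse_percent(r, series), _safe_p(pred, series)))
    for name, series in obs.scfa_mM.items():
        if name not in sim.species.columns:
            unmatched.append(name)
            continue
        info = sim.community.registry[name]
        gl = np.interp(obs.times, sim.times, sim.species_trajectory(name))
        pred = _truncate_mM(gl_to_mM(gl, info.molar_mass), detection_limit_mM)
        ob = _truncate_mM(series, detection_limit_mM)
        r = rmse(pred, ob)
        rows.append((name, "scfa", r, rmse_percent(r, ob), _safe_p(pred, ob)))
    table = pd.DataFrame(rows, columns=["variable", "kind", "rmse", "rmse_pct", "lm_p"])
    return ComparisonReport(table=table, unmatched=unmatched)


def _safe_p(pred: np.ndarray, obs: np.ndarray) -> float:
    try:
        return lm_fit(pred, obs).p_value
    except ValidationError:
        return float("nan")


# ---------------------------------------------------------------------------
# Community composition summary
# ---------------------------------------------------------------------------


def core_summary(
    abundance_table: pd.DataFrame,
    core_list: Sequence[str] | None = None,
) -> dict:
    """Core-microbiota share of each sample's community.

    ``abundance_table``: rows = genera (index) including an "Others" row,
    columns = samples, values = relative abundance in percent summing to
    ~100 per sample.  ``core_list`` defaults to every row except "Others".
    The core fraction is computed as 100 minus the non-core share
    (equivalently the sum of the core genera, but robust to the rounding
    of individually printed per-genus values).  Returns per-sample core
    fractions plus their mean and sample (n-1) SD.
    """
    if core_list is None:
        core_list = [g for g in abundance_table.index if g.lower() != "others"]
    warnings = [
        f"genus {g!r} missing from table; treated as 0"
        for g in core_list if g not in abundance_table.index
    ]
    non_core = [g for g in abundance_table.index if g not in set(core_list)]
    fractions = 100.0 - abundance_table.loc[non_core].fillna(0.0).sum(axis=0)
    values = fractions.to_numpy(dtype=float)
    return {
        "per_sample": {c: float(v) for c, v in fractions.items()},
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else float("nan"),
        "warnings": warnings,
    }


# ---------------------------------------------------------------------------
# Half-saturation calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KCoordinate:
    """Addresses one half-saturation constant in a community."""

    group: str
    pathway_id: str
    species: str


def k_coordinates(community: Community) -> list[KCoordinate]:
    """Every tunable K (essential/substitutable/boosting entries), in order."""
    out = []
    for g in community.groups:
        for p in g.pathways:
            for sp, e in p.entries.items():
                if e.half_sat is not None:
                    out.append(KCoordinate(g.name, p.pathway_id, sp))
    return out


def with_half_sats(
    community: Community, values: Mapping[KCoordinate, float]
) -> Community:
    """A copy of the community with the addressed K values replaced."""
    groups = []
    for g in community.groups:
        pathways = []
        for p in g.pathways:
            entries = {}
            for sp, e in p.entries.items():
                coord = KCoordinate(g.name, p.pathway_id, sp)
                if coord in values:
                    entries[sp] = replace(e, half_sat=float(values[coord]))
                else:
                    entries[sp] = e
            pathways.append(type(p)(p.pathway_id, p.mu_max, entries))
        groups.append(type(g)(g.name, pathways, g.ph_corners))
    return Community(community.name, groups, dict(community.registry),
                     dict(community.initial_fractions))


@dataclass
class CalibrationResult:
    k_values: dict[KCoordinate, float]
    score: float
    trace: list[tuple[int, float]]  # (evaluations used, best score so far)
    n_evaluations: int


def calibrate_K(
    community: Community,
    scenario: ChemostatScenario,
    obs: ObservationSet,
    bounds: tuple[float, float] = (1e-4, 1.0),
    budget: int = 200,
    seed: int = 0,
    k_init: float = 0.001,
) -> CalibrationResult:
    """Empirical half-saturation calibration against an observation set.

    Every K starts at ``k_init`` (the 0.001 g/L convention).  The search
    then cycles through the K coordinates, proposing one log-uniform draw
    at a time inside a window around the current best value (the window
    starts spanning the full ``bounds`` and shrinks each full pass), and
    keeps a proposal only if it lowers the summed per-variable RMSE of
    :func:`compare`.  Proposals whose simulation fails score as infinite.
    Deterministic given ``seed``; ``budget`` counts proposal evaluations,
    so a budget of 0 returns the initial vector.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValidationError(f"bounds must satisfy 0 < lo < hi, got {bounds}")
    if budget < 0:
        raise ValidationError("budget must be >= 0")
    coords = k_coordinates(community)
    if not coords:
        raise ValidationError("community has no tunable half-saturation constants")
    rng = np.random.default_rng(seed)
    llo, lhi = math.log10(lo), math.log10(hi)

    def score(kvec: dict[KCoordinate, float]) -> float:
        try:
            sim = simulate(scenario, with_half_sats(community, kvec))
            rep = compare(sim, obs)
            s = float(rep.table["rmse"].sum())
            return s if math.isfinite(s) else float("inf")
        except Exception:
            return float("inf")

    k = {c: float(np.clip(k_init, lo, hi)) for c in coords}
    best = score(k)
    trace = [(0, best)]
    width = lhi - llo  # half-width of the proposal window, log10 units
    n = len(coords)
    for i in range(budget):
        if i > 0 and i % n == 0:
            width = max(0.85 * width, 0.05)
        c = coords[i % n]
        center = math.log10(k[c])
        prop = float(np.clip(center + rng.uniform(-width, width), llo, lhi))
        cand = dict(k)
        cand[c] = 10.0 ** prop
        s = score(cand)
        if s < best:
            best, k = s, cand
        trace.append((i + 1, best))
    return CalibrationResult(k_values=k, score=best, trace=trace,
                             n_evaluations=budget + 1)
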