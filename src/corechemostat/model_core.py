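"""Domain types and kinetic rate laws for the core-microbiota chemostat model.

The community is described by microbial *groups* (genera plus an aggregated
"others" group), each carrying one or more metabolic pathways.  A pathway
lists the chemical species it touches, classified as essential (Se),
substitutable (S), water (Sw), boosting (Sb) resources or products (P), with
per-entry molar mass ``m``, molecule count ``n``, half-saturation constant
``K`` (g/L) and biomass yield ``Y`` (g biomass per g resource).

Growth follows Monod kinetics modulated by a trapezoidal pH limitation
("pH corners").  Uptake, water uptake and metabolite production are tied
together so that, per strain,

    sum_z M_z + mu = sum_i U_i + U_w

holds identically: whatever resource mass is taken up and not fixed into
biomass leaves as products, apportioned by product stoichiometric mass
shares ``m_z n_z / sum_k m_k n_k``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RESOURCE_CLASSES",
    "GROWTH_CLASSES",
    "ValidationError",
    "ConfigurationError",
    "IntegrationError",
    "SpeciesEntry",
    "PathwaySpec",
    "GroupSpec",
    "StrainSpec",
    "SpeciesInfo",
    "StateVector",
    "RatesBreakdown",
    "CompiledCommunity",
    "ph_limitation",
    "growth_rate",
    "uptake_rates",
    "metabolite_production",
    "strain_rates",
    "ode_rhs",
    "make_strains",
]

#: The five recognised resource classes (microPop-style Rtype labels
#: Se / S / Sw / Sb / P map onto these in the CSV frames).
RESOURCE_CLASSES = ("essential", "substitutable", "water", "boosting", "product")

#: Classes whose entries drive growth kinetics and are consumed via yields.
GROWTH_CLASSES = ("essential", "substitutable")


class ValidationError(ValueError):
    """A parameter frame or domain object violates its invariants."""


class ConfigurationError(ValueError):
    """A scenario/community wiring problem (e.g. unresolved species name)."""


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced out-of-tolerance negative states."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesEntry:
    """One chemical species inside a pathway.

    Parameters
    ----------
    rclass
        Resource class, one of :data:`RESOURCE_CLASSES`.
    molar_mass
        Molar mass ``m`` in g/mol.
    n_molecules
        Stoichiometric molecule count ``n`` (dimensionless).
    half_sat
        Monod half-saturation constant ``K`` in g/L.  Required for
        essential, substitutable and boosting entries; ignored otherwise.
    yield_
        Biomass yield ``Y`` in g biomass per g resource, in (0, 1].
        Required for essential and substitutable entries.
    """

    rclass: str
    molar_mass: float
    n_molecules: float
    half_sat: float | None = None
    yield_: float | None = None

    def __post_init__(self) -> None:
        if self.rclass not in RESOURCE_CLASSES:
            raise ValidationError(
                f"unknown resource class {self.rclass!r}; "
                f"expected one of {RESOURCE_CLASSES}"
            )
        if not self.molar_mass > 0:
            raise ValidationError(f"molar_mass must be > 0, got {self.molar_mass}")
        if not self.n_molecules > 0:
            raise ValidationError(f"n_molecules must be > 0, got {self.n_molecules}")
        if self.rclass in GROWTH_CLASSES or self.rclass == "boosting":
            if self.half_sat is None or not self.half_sat > 0:
                raise ValidationError(
                    f"half_sat must be > 0 for {self.rclass} entries, got {self.half_sat}"
                )
        if self.rclass in GROWTH_CLASSES:
            if self.yield_ is None or not (0.0 < self.yield_ <= 1.0):
                raise ValidationError(
                    f"yield must be in (0, 1] for {self.rclass} entries, got {self.yield_}"
                )

    @property
    def mn(self) -> float:
        """Stoichiometric mass ``m * n`` (g/mol-reaction)."""
        return self.molar_mass * self.n_molecules


@dataclass
class PathwaySpec:
    """A metabolic pathway: stoichiometry plus its maximum specific growth rate."""

    pathway_id: str
    mu_max: float
    entries: dict[str, SpeciesEntry]

    def __post_init__(self) -> None:
        if not self.mu_max > 0:
            raise ValidationError(
                f"pathway {self.pathway_id!r}: mu_max must be > 0, got {self.mu_max}"
            )
        classes = [e.rclass for e in self.entries.values()]
        if not any(c in GROWTH_CLASSES for c in classes):
            raise ValidationError(
                f"pathway {self.pathway_id!r} needs at least one essential or "
                "substitutable resource entry"
            )
        if "product" not in classes:
            raise ValidationError(
                f"pathway {self.pathway_id!r} needs at least one product entry"
            )

    def species_of(self, *classes: str) -> list[str]:
        return [s for s, e in self.entries.items() if e.rclass in classes]

    @property
    def resources(self) -> list[str]:
        return self.species_of(*GROWTH_CLASSES)

    @property
    def products(self) -> list[str]:
        return self.species_of("product")


def _check_corners(corners: Sequence[float], owner: str) -> tuple[float, float, float, float]:
    c = tuple(float(x) for x in corners)
    if len(c) != 4:
        raise ValidationError(f"{owner}: expected 4 pH corners, got {len(c)}")
    c1, c2, c3, c4 = c
    if not (c1 < c2 <= c3 < c4):
        raise ValidationError(
            f"{owner}: pH corners must satisfy c1 < c2 <= c3 < c4, got {c}"
        )
    return c


@dataclass
class GroupSpec:
    """A microbial group: its pathways and pH tolerance trapezoid."""

    name: str
    pathways: list[PathwaySpec]
    ph_corners: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValidationError(f"group {self.name!r} has no pathways")
        self.ph_corners = _check_corners(self.ph_corners, f"group {self.name!r}")
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"group {self.name!r} has duplicate pathway ids")

    @property
    def mu_max(self) -> list[float]:
        return [p.mu_max for p in self.pathways]

    def species(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= set(p.entries)
        return out


@dataclass
class StrainSpec:
    """A (possibly trait-perturbed) strain of a parent group."""

    parent: str
    strain_id: str
    pathways: list[PathwaySpec]
    ph_corners: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        self.ph_corners = _check_corners(self.ph_corners, f"strain {self.strain_id!r}")


@dataclass(frozen=True)
class SpeciesInfo:
    """Registry record for a chemical species."""

    molar_mass: float
    kind: str  # "resource" | "metabolite" | "water"


@dataclass
class StateVector:
    """Named concentrations (g/L) split into microbes and chemical species."""

    microbes: dict[str, float]
    species: dict[str, float]

    def __post_init__(self) -> None:
        for name, v in {**self.microbes, **self.species}.items():
            if v < 0:
                raise ValidationError(f"negative concentration for {name!r}: {v}")

    @property
    def dimension(self) -> int:
        return len(self.microbes) + len(self.species)

    def partition(self, registry: Mapping[str, SpeciesInfo]) -> tuple[dict, dict, dict]:
        """Split species into (resources, metabolites) using a registry."""
        res = {k: v for k, v in self.species.items() if registry[k].kind == "resource"}
        met = {k: v for k, v in self.species.items() if registry[k].kind == "metabolite"}
        return self.microbes, res, met


@dataclass
class RatesBreakdown:
    """Specific rates of one strain at one state (all per g biomass per h)."""

    strain_id: str
    mu_by_pathway: dict[str, float]
    mu_total: float
    uptake: dict[str, float]
    water_uptake: float
    production: dict[str, float]

    def mass_balance_residual(self) -> float:
        """``sum_z M_z + mu - sum_i U_i - U_w`` (should be ~0)."""
        return (
            sum(self.production.values())
            + self.mu_total
            - sum(self.uptake.values())
            - self.water_uptake
        )


# ---------------------------------------------------------------------------
# pH limitation
# ---------------------------------------------------------------------------


def ph_limitation(ph: float, corners: Sequence[float]) -> float:
    """Trapezoidal growth limitation factor in [0, 1].

    Zero at or outside the outer corners (growth impossible), one on the
    optimal plateau between the two middle corners, linear in between.
    """
    c1, c2, c3, c4 = _check_corners(corners, "ph_limitation")
    if ph <= c1 or ph >= c4:
        return 0.0
    if c2 <= ph <= c3:
        return 1.0
    if ph < c2:
        return (ph - c1) / (c2 - c1)
    return (c4 - ph) / (c4 - c3)


# ---------------------------------------------------------------------------
# Compiled community: vectorized kinetics over all strains/pathways
# ---------------------------------------------------------------------------


class CompiledCommunity:
    """Array-backed view of a set of strains over an ordered species list.

    All kinetic quantities for every pathway of every strain are evaluated
    with dense numpy operations; this single kernel backs both the public
    per-strain rate functions and the ODE right-hand side.

    Water handling: a pathway's water entry contributes to the mass balance
    through ``U_w`` whether or not "water" appears in ``species``.  If it
    does appear, water uptake is additionally debited from that state
    variable (used for closed-system mass-conservation checks).
    """

    def __init__(self, strains: Sequence[StrainSpec], species: Sequence[str]):
        self.strains = list(strains)
        self.species = list(species)
        self.species_index = {s: i for i, s in enumerate(self.species)}
        J = len(self.strains)
        self.strain_index = {s.strain_id: j for j, s in enumerate(self.strains)}
        if len(self.strain_index) != J:
            raise ConfigurationError("duplicate strain ids in community")

        paths: list[tuple[int, PathwaySpec]] = []
        for j, strain in enumerate(self.strains):
            for p in strain.pathways:
                paths.append((j, p))
        P, S = len(paths), len(self.species)

        self.path_strain = np.array([j for j, _ in paths], dtype=int)
        self.path_ids = [(self.strains[j].strain_id, p.pathway_id) for j, p in paths]
        self.mu_max = np.array([p.mu_max for _, p in paths])
        self.corners = np.array([s.ph_corners for s in self.strains])

        self.ess_mask = np.zeros((P, S), dtype=bool)
        self.sub_mask = np.zeros((P, S), dtype=bool)
        self.boost_mask = np.zeros((P, S), dtype=bool)
        self.K = np.ones((P, S))
        self.Y = np.ones((P, S))
        self.mn = np.zeros((P, S))
        self.prod_share = np.zeros((P, S))
        self.water_mn = np.zeros(P)
        self.growth_mn_sum = np.zeros(P)
        self.water_index = self.species_index.get("water")

        for ip, (j, p) in enumerate(paths):
            prod_mn = 0.0
            for name, e in p.entries.items():
                if e.rclass == "water":
                    self.water_mn[ip] += e.mn
                    continue
                if name not in self.species_index:
                    raise ConfigurationError(
                        f"strain {self.strains[j].strain_id!r}, pathway "
                        f"{p.pathway_id!r}: species {name!r} not in the "
                        "community species list"
                    )
                k = self.species_index[name]
                self.mn[ip, k] = e.mn
                if e.rclass == "essential":
                    self.ess_mask[ip, k] = True
                    self.K[ip, k] = e.half_sat
                    self.Y[ip, k] = e.yield_
                elif e.rclass == "substitutable":
                    self.sub_mask[ip, k] = True
                    self.K[ip, k] = e.half_sat
                    self.Y[ip, k] = e.yield_
                elif e.rclass == "boosting":
                    self.boost_mask[ip, k] = True
                    self.K[ip, k] = e.half_sat
                elif e.rclass == "product":
                    self.prod_share[ip, k] = e.mn
                    prod_mn += e.mn
            self.growth_mn_sum[ip] = (
                self.mn[ip][self.ess_mask[ip] | self.sub_mask[ip]].sum()
            )
            if prod_mn > 0:
                self.prod_share[ip] /= prod_mn

        self.has_ess = self.ess_mask.any(axis=1)
        self.has_sub = self.sub_mask.any(axis=1)
        self.n_strains = J
        self.n_paths = P
        self.n_species = S
        # strain aggregation matrix (J, P)
        self._agg = np.zeros((J, P))
        self._agg[self.path_strain, np.arange(P)] = 1.0

    # -- kinetics ----------------------------------------------------------

    def ph_factors(self, ph: float) -> np.ndarray:
        """Per-strain trapezoidal pH limitation factors."""
        c = self.corners
        lam = np.zeros(self.n_strains)
        rising = (ph > c[:, 0]) & (ph < c[:, 1])
        plateau = (ph >= c[:, 1]) & (ph <= c[:, 2])
        falling = (ph > c[:, 2]) & (ph < c[:, 3])
        lam[rising] = (ph - c[rising, 0]) / (c[rising, 1] - c[rising, 0])
        lam[plateau] = 1.0
        lam[falling] = (c[falling, 3] - ph) / (c[falling, 3] - c[falling, 2])
        return lam

    def rates(self, conc: np.ndarray, ph: float):
        """Specific rates for every pathway/strain at species concentrations.

        Parameters
        ----------
        conc
            Nonnegative species concentrations, g/L, ordered as ``self.species``.
        ph
            Current pH.

        Returns
        -------
        mu_path : (P,) per-pathway specific growth rates, 1/h
        mu : (J,) per-strain totals
        U : (P, S) specific uptake rates, g resource / g biomass / h
        Uw : (P,) specific water uptake rates
        M : (P, S) specific production rates, g product / g biomass / h
        """
        conc = np.maximum(np.asarray(conc, dtype=float), 0.0)
        monod = conc[None, :] / (self.K + conc[None, :])

        ess = np.where(self.ess_mask, monod, 2.0).min(axis=1)
        ess = np.where(self.has_ess, ess, 1.0)

        sub_conc = np.where(self.sub_mask, conc[None, :], 0.0)
        w_kin = sub_conc * monod  # S_r * Monod_r, substitutable entries only
        denom = w_kin.sum(axis=1)
        total_sub = sub_conc.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            subf = np.where(total_sub > 0, denom / np.where(total_sub > 0, total_sub, 1.0), 0.0)
        subf = np.where(self.has_sub, subf, 1.0)

        boost = np.where(self.boost_mask, 1.0 + 0.5 * monod, 1.0).prod(axis=1)

        lam = self.ph_factors(ph)
        mu_path = self.mu_max * lam[self.path_strain] * ess * subf * boost

        # uptake apportionment weights: stoichiometric mass times kinetic
        # activity (1 for essential; within-class share for substitutable)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(denom[:, None] > 0, w_kin / np.where(denom, denom, 1.0)[:, None], 0.0)
        w = self.mn * (self.ess_mask + share * self.sub_mask)
        wsum = w.sum(axis=1)
        wsafe = np.where(wsum > 0, wsum, 1.0)
        U = w * (mu_path / wsafe)[:, None] / self.Y
        U[mu_path <= 0] = 0.0

        Uw = self.water_mn / self.growth_mn_sum * U.sum(axis=1)
        resid = U.sum(axis=1) + Uw - mu_path
        M = self.prod_share * resid[:, None]

        mu = self._agg @ mu_path
        return mu_path, mu, U, Uw, M

    # -- ODE right-hand side ----------------------------------------------

    def rhs(
        self,
        t: float,
        y: np.ndarray,
        dilution_rate: float,
        inflow_species: np.ndarray,
        inflow_microbes: np.ndarray,
        ph_at,
    ) -> np.ndarray:
        """Chemostat mass balances: d/dt of [strain biomasses, species].

        Microbes:   dB_j/dt = B_j (mu_j - D) + D B_in,j
        Species:    dC_s/dt = D (C_in,s - C_s) + sum_j (M_js - U_js) B_j
        (a species consumed by cross-feeders and produced by others gets
        both contributions; tracked water is additionally debited by U_w).
        """
        J, S = self.n_strains, self.n_species
        B = np.maximum(y[:J], 0.0)
        C = np.maximum(y[J:], 0.0)
        ph = ph_at(t) if callable(ph_at) else ph_at
        _, mu, U, Uw, M = self.rates(C, ph)
        net = M - U  # (P, S)
        Bp = B[self.path_strain]
        dC = dilution_rate * (inflow_species - C) + net.T @ Bp
        if self.water_index is not None:
            dC[self.water_index] -= Uw @ Bp
        dB = B * (mu - dilution_rate) + dilution_rate * inflow_microbes
        return np.concatenate([dB, dC])


# ---------------------------------------------------------------------------
# Public per-strain operations (thin wrappers over the compiled kernel)
# ---------------------------------------------------------------------------


def _single(strain: StrainSpec, state: Mapping[str, float] | StateVector):
    species_conc = state.species if isinstance(state, StateVector) else dict(state)
    names = set(species_conc)
    for p in strain.pathways:
        for s, e in p.entries.items():
            if e.rclass != "water" and s not in names:
                raise ConfigurationError(
                    f"strain {strain.strain_id!r}, pathway {p.pathway_id!r}: "
                    f"species {s!r} missing from the state"
                )
    order = list(species_conc)
    cc = CompiledCommunity([strain], order)
    conc = np.array([species_conc[s] for s in order])
    return cc, order, conc


def strain_rates(
    strain: StrainSpec, state: Mapping[str, float] | StateVector, ph: float
) -> RatesBreakdown:
    """Full specific-rate breakdown (growth, uptake, water, production)."""
    cc, order, conc = _single(strain, state)
    mu_path, mu, U, Uw, M = cc.rates(conc, ph)
    Usum = U.sum(axis=0)
    Msum = M.sum(axis=0)
    return RatesBreakdown(
        strain_id=strain.strain_id,
        mu_by_pathway={p.pathway_id: float(m) for p, m in zip(strain.pathways, mu_path)},
        mu_total=float(mu[0]),
        uptake={s: float(u) for s, u in zip(order, Usum) if u != 0.0},
        water_uptake=float(Uw.sum()),
        production={s: float(m) for s, m in zip(order, Msum) if m != 0.0},
    )


def growth_rate(
    strain: StrainSpec, state: Mapping[str, float] | StateVector, ph: float
) -> tuple[dict[str, float], float]:
    """Per-pathway and total specific growth rate (1/h)."""
    r = strain_rates(strain, state, ph)
    return r.mu_by_pathway, r.mu_total


def uptake_rates(
    strain: StrainSpec, state: Mapping[str, float] | StateVector, ph: float
) -> tuple[dict[str, float], float]:
    """Specific resource uptake rates and water uptake (g/g/h)."""
    r = strain_rates(strain, state, ph)
    return r.uptake, r.water_uptake


def metabolite_production(
    strain: StrainSpec, state: Mapping[str, float] | StateVector, ph: float
) -> dict[str, float]:
    """Specific production rate of each product (g/g/h)."""
    return strain_rates(strain, state, ph).production


def ode_rhs(
    t: float,
    state: StateVector,
    strains: Sequence[StrainSpec],
    dilution_rate: float,
    inflow_species: Mapping[str, float] | None = None,
    inflow_microbes: Mapping[str, float] | None = None,
    ph: float = 6.4,
) -> StateVector:
    """Named-state convenience wrapper around the chemostat balances."""
    order = list(state.species)
    cc = CompiledCommunity(strains, order)
    if set(state.microbes) != set(s.strain_id for s in strains):
        raise ConfigurationError("state microbes do not match the strain list")
    y = np.concatenate(
        [
            np.array([state.microbes[s.strain_id] for s in strains]),
            np.array([state.species[s] for s in order]),
        ]
    )
    inflow_species = inflow_species or {}
    inflow_microbes = inflow_microbes or {}
    sin = np.array([float(inflow_species.get(s, 0.0)) for s in order])
    bin_ = np.array([float(inflow_microbes.get(s.strain_id, 0.0)) for s in strains])
    dy = cc.rhs(t, y, dilution_rate, sin, bin_, ph)
    J = len(strains)
    d_microbes = {s.strain_id: float(v) for s, v in zip(strains, dy[:J])}
    d_species = {n: float(v) for n, v in zip(order, dy[J:])}
    out = StateVector.__new__(StateVector)  # skip nonnegativity check: derivative
    out.microbes = d_microbes
    out.species = d_species
    return out


# ---------------------------------------------------------------------------
# Strain generation
# ---------------------------------------------------------------------------


def make_strains(
    group: GroupSpec,
    n_strains: int = 1,
    variability: float = 0.1,
    seed: int | np.random.Generator | None = None,
) -> list[StrainSpec]:
    """Draw ``n_strains`` trait-perturbed strains of ``group``.

    ``mu_max`` and every half-saturation constant are multiplied by
    independent uniform factors in ``[1 - variability, 1 + variability]``;
    the two inner pH corners shift by up to ``±variability`` pH units
    (redrawn if the corner ordering would break).  ``variability = 0``
    reproduces the parent exactly; the draw is deterministic per seed.
    """
    if n_strains < 1:
        raise ValidationError(f"n_strains must be >= 1, got {n_strains}")
    if not (0.0 <= variability < 1.0):
        raise ValidationError(f"variability must be in [0, 1), got {variability}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    strains = []
    for k in range(n_strains):
        factor = lambda: 1.0 + variability * rng.uniform(-1.0, 1.0)  # noqa: E731
        pathways = []
        for p in group.pathways:
            entries = {}
            for name, e in p.entries.items():
                if e.half_sat is not None:
                    entries[name] = replace(e, half_sat=e.half_sat * factor())
                else:
                    entries[name] = e
            pathways.append(
                PathwaySpec(p.pathway_id, p.mu_max * factor(), entries)
            )
        c1, _, _, c4 = group.ph_corners
        while True:
            c2 = group.ph_corners[1] + variability * rng.uniform(-1.0, 1.0)
            c3 = group.ph_corners[2] + variability * rng.uniform(-1.0, 1.0)
            if c1 < c2 <= c3 < c4:
                break
        sid = group.name if n_strains == 1 else f"{group.name}.{k + 1}"
        strains.append(StrainSpec(group.name, sid, pathways, (c1, c2, c3, c4)))
    return strains
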