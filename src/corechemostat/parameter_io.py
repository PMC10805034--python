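"""Reading, writing and validating group parameter frames and communities.

A group's parameters live in one CSV frame (microPop-style layout): fixed
columns ``parameter, pathway, units, value`` followed by one column per
chemical species the group touches.  Rows come in per-pathway blocks
(``Rtype, molarMass, numMolecules, stoichiomProduct, halfSat, yield,
maxGrowthRate``) plus four group-level ``pHcorner`` rows.  Rtype labels are
the classification tags Se (essential), S (substitutable), Sw (water),
Sb (boosting) and P (product).

A community bundles the member group specs with a species registry
(molar masses, resource vs metabolite kind) and default initial relative
abundances; ``builtin_community`` ships the packaged synthetic stand-in
for the study's 17-group parameter library.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import _fixture_community as _fix
from .model_core import (
    GroupSpec,
    PathwaySpec,
    SpeciesEntry,
    SpeciesInfo,
    ValidationError,
)

__all__ = [
    "Community",
    "CommunityManifest",
    "read_group_frame",
    "write_group_frame",
    "builtin_community",
    "validate_community",
    "write_community",
    "read_community",
]

_RTYPE_TO_CLASS = {
    "Se": "essential",
    "S": "substitutable",
    "Sw": "water",
    "Sb": "boosting",
    "P": "product",
}
_CLASS_TO_RTYPE = {v: k for k, v in _RTYPE_TO_CLASS.items()}

_PATHWAY_ROWS = [
    "Rtype",
    "molarMass",
    "numMolecules",
    "stoichiomProduct",
    "halfSat",
    "yield",
    "maxGrowthRate",
]
_ROW_UNITS = {
    "molarMass": "g/mol",
    "halfSat": "g/L",
    "yield": "g/g",
    "maxGrowthRate": "1/h",
}


@dataclass
class CommunityManifest:
    """Members (name, frame file, strains per group) plus species registry."""

    name: str
    members: list[tuple[str, str, int]]
    registry: dict[str, SpeciesInfo]

    def __post_init__(self) -> None:
        names = [m[0] for m in self.members]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate member names in manifest")


@dataclass
class Community:
    """A ready-to-simulate community: group specs + registry + composition."""

    name: str
    groups: list[GroupSpec]
    registry: dict[str, SpeciesInfo]
    initial_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    def group(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def tracked_species(self, track_water: bool = False) -> list[str]:
        """Ordered state species: resources, then metabolites (then water)."""
        out = [s for s, i in self.registry.items() if i.kind == "resource"]
        out += [s for s, i in self.registry.items() if i.kind == "metabolite"]
        if track_water and "water" in self.registry:
            out.append("water")
        return out


# ---------------------------------------------------------------------------
# Frame writer / reader
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


def write_group_frame(spec: GroupSpec, path: str | Path | None = None) -> str:
    """Serialize a GroupSpec to its CSV frame; returns the CSV text.

    Column order is deterministic (species in order of first appearance
    across pathways), so two writes of the same spec are byte-identical.
    """
    species: list[str] = []
    for p in spec.pathways:
        for s in p.entries:
            if s not in species:
                species.append(s)
    header = ["parameter", "pathway", "units", "value"] + species
    rows: list[list[str]] = []

    def cell(e: SpeciesEntry | None, row: str) -> str:
        if e is None:
            return ""
        if row == "Rtype":
            return _CLASS_TO_RTYPE[e.rclass]
        if row == "molarMass":
            return _fmt(e.molar_mass)
        if row == "numMolecules":
            return "" if e.rclass == "product" else _fmt(e.n_molecules)
        if row == "stoichiomProduct":
            return _fmt(e.n_molecules) if e.rclass == "product" else ""
        if row == "halfSat":
            return _fmt(e.half_sat) if e.half_sat is not None else ""
        if row == "yield":
            return _fmt(e.yield_) if e.yield_ is not None else ""
        return ""

    for p in spec.pathways:
        for row in _PATHWAY_ROWS:
            units = _ROW_UNITS.get(row, "")
            value = _fmt(p.mu_max) if row == "maxGrowthRate" else ""
            cells = [cell(p.entries.get(s), row) if row != "maxGrowthRate" else ""
                     for s in species]
            rows.append([row, p.pathway_id, units, value] + cells)
    for i, c in enumerate(spec.ph_corners, start=1):
        rows.append([f"pHcorner{i}", "", "pH", _fmt(c)] + [""] * len(species))

    buf = io.StringIO()
    buf.write(",".join(header) + "\n")
    for r in rows:
        buf.write(",".join(r) + "\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def _num(cell: str, where: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ValidationError(f"{where}: non-numeric cell {cell!r}") from None


def read_group_frame(path: str | Path, name: str | None = None) -> GroupSpec:
    """Parse and fully validate a group parameter frame."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"parameter", "pathway", "units", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path.name}: missing fixed columns {sorted(required - set(df.columns))}"
        )
    species = [c for c in df.columns if c not in required]
    name = name or path.stem

    def rows_for(pid: str, param: str) -> pd.Series | None:
        sel = df[(df["pathway"] == pid) & (df["parameter"] == param)]
        if sel.empty:
            return None
        return sel.iloc[0]

    pathway_ids: list[str] = []
    for pid in df["pathway"]:
        if pid and pid not in pathway_ids:
            pathway_ids.append(pid)
    if not pathway_ids:
        raise ValidationError(f"{path.name}: no pathway blocks found")

    pathways = []
    for pid in pathway_ids:
        block = {param: rows_for(pid, param) for param in _PATHWAY_ROWS}
        for param in ("Rtype", "molarMass", "maxGrowthRate"):
            if block[param] is None:
                raise ValidationError(
                    f"{path.name}, pathway {pid!r}: missing row {param!r}"
                )
        entries: dict[str, SpeciesEntry] = {}
        for sp in species:
            rtype = block["Rtype"][sp].strip()
            if not rtype:
                continue
            if rtype not in _RTYPE_TO_CLASS:
                raise ValidationError(
                    f"{path.name}, pathway {pid!r}, column {sp!r}: "
                    f"unknown Rtype {rtype!r} (expected one of "
                    f"{sorted(_RTYPE_TO_CLASS)})"
                )
            rclass = _RTYPE_TO_CLASS[rtype]
            where = f"{path.name}, pathway {pid!r}, column {sp!r}"
            m = _num(block["molarMass"][sp], where + ", row molarMass")
            if rclass == "product":
                row = block["stoichiomProduct"]
                if row is None or not row[sp].strip():
                    raise ValidationError(f"{where}: missing stoichiomProduct")
                n = _num(row[sp], where + ", row stoichiomProduct")
            else:
                row = block["numMolecules"]
                if row is None or not row[sp].strip():
                    raise ValidationError(f"{where}: missing numMolecules")
                n = _num(row[sp], where + ", row numMolecules")
            half_sat = None
            yield_ = None
            if rclass in ("essential", "substitutable", "boosting"):
                row = block["halfSat"]
                if row is None or not row[sp].strip():
                    raise ValidationError(f"{where}: missing halfSat")
                half_sat = _num(row[sp], where + ", row halfSat")
            if rclass in ("essential", "substitutable"):
                row = block["yield"]
                if row is None or not row[sp].strip():
                    raise ValidationError(f"{where}: missing yield")
                yield_ = _num(row[sp], where + ", row yield")
            try:
                entries[sp] = SpeciesEntry(rclass, m, n, half_sat, yield_)
            except ValidationError as err:
                raise ValidationError(f"{where}: {err}") from None
        mu = _num(block["maxGrowthRate"]["value"],
                  f"{path.name}, pathway {pid!r}, row maxGrowthRate")
        try:
            pathways.append(PathwaySpec(pid, mu, entries))
        except ValidationError as err:
            raise ValidationError(f"{path.name}, pathway {pid!r}: {err}") from None

    corners = []
    for i in range(1, 5):
        sel = df[df["parameter"] == f"pHcorner{i}"]
        if sel.empty:
            raise ValidationError(f"{path.name}: missing row pHcorner{i}")
        corners.append(_num(sel.iloc[0]["value"], f"{path.name}, row pHcorner{i}"))
    try:
        return GroupSpec(name, pathways, tuple(corners))
    except ValidationError as err:
        raise ValidationError(f"{path.name}: {err}") from None


# ---------------------------------------------------------------------------
# Built-in communities and validation
# ---------------------------------------------------------------------------


def builtin_community(which: str = "bioreactor") -> Community:
    """The packaged synthetic community library.

    ``bioreactor``: the 16 modeled core genera plus "others" (17 groups);
    ``cm_only``: the core genera without "others";
    ``others_only``: the single aggregated "others" group (10 functional
    pathways).  Initial relative abundances come from the in-silico
    community composition column, renormalized over the included groups'
    registry total.
    """
    groups_all = _fix.fixture_groups()
    if which == "bioreactor":
        names = _fix.CORE_GENERA + ["others"]
    elif which == "cm_only":
        names = list(_fix.CORE_GENERA)
    elif which == "others_only":
        names = ["others"]
    else:
        raise ValidationError(
            f"unknown builtin community {which!r}; expected bioreactor, "
            "cm_only or others_only"
        )
    fractions = {n: _fix.IN_SILICO_FRACTIONS[n] for n in names}
    return Community(
        name=which,
        groups=[groups_all[n] for n in names],
        registry=dict(_fix.SPECIES_REGISTRY),
        initial_fractions=fractions,
    )


def validate_community(community: Community) -> list[str]:
    """Cross-check every group frame against the species registry.

    Returns a list of human-readable issues; an empty list means clean.
    """
    issues: list[str] = []
    seen: set[str] = set()
    for g in community.groups:
        if g.name in seen:
            issues.append(f"duplicate group name {g.name!r}")
        seen.add(g.name)
        for p in g.pathways:
            for sp in p.entries:
                if sp not in community.registry:
                    issues.append(
                        f"group {g.name!r}, pathway {p.pathway_id!r}: "
                        f"unresolved species {sp!r}"
                    )
    for sp, info in community.registry.items():
        if not info.molar_mass > 0:
            issues.append(f"species {sp!r}: missing or non-positive molar mass")
    for name in community.initial_fractions:
        if name not in seen:
            issues.append(f"initial fraction given for unknown group {name!r}")
    return issues


# ---------------------------------------------------------------------------
# Community directory round-trip
# ---------------------------------------------------------------------------


def write_community(community: Community, directory: str | Path) -> Path:
    """Write frames plus a manifest file into a community directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    members = []
    for g in community.groups:
        fname = f"{g.name}.csv"
        write_group_frame(g, directory / fname)
        members.append({"group": g.name, "frame": fname})
    manifest = {
        "name": community.name,
        "members": members,
        "species": {
            sp: {"molar_mass": info.molar_mass, "kind": info.kind}
            for sp, info in community.registry.items()
        },
        "initial_fractions_percent": dict(community.initial_fractions),
    }
    out = directory / "manifest.yaml"
    out.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


def read_community(directory: str | Path) -> Community:
    """Load a community directory written by :func:`write_community`."""
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    registry = {
        sp: SpeciesInfo(d["molar_mass"], d["kind"])
        for sp, d in manifest["species"].items()
    }
    groups = [
        read_group_frame(directory / m["frame"], name=m["group"])
        for m in manifest["members"]
    ]
    return Community(
        name=manifest.get("name", directory.name),
        groups=groups,
        registry=registry,
        initial_fractions=dict(manifest.get("initial_fractions_percent", {})),
    )
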