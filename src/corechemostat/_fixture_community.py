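"""Synthetic parameter library for the packaged pig fecal core-microbiota model.

The published model drew its per-genus stoichiometry and kinetics from
culture-based supplementary tables that are not redistributable, so the
values below are a synthetic stand-in: a fully specified community with the
same architecture (16 core genera + an aggregated "others" group organised
into 10 metabolic functional pathways, 4 resource pools, 13 metabolites)
and the same qualitative behaviour under the continuous-fermentation
conditions (dilution rate 0.111 1/h, pH ~6.4):

* Prevotella, Megasphaera, Succinivibrio, Blautia, Ruminococcus and
  "others" maintain growth at the dilution rate and persist;
* the remaining, more fastidious genera have mu_max below the dilution
  rate and wash out;
* lactate is produced (Lactobacillus, Streptococcus, Turicibacter, and an
  "others" functional pathway) but is cross-fed away by Megasphaera and
  "others" fast enough to stay below the 0.1 mM detection limit;
* saccharolytic yields are anchored at 0.333 g biomass per g substrate,
  half-saturation constants start from the 0.001 g/L convention and were
  set within biologically plausible ranges.
"""

from __future__ import annotations

from .model_core import GroupSpec, PathwaySpec, SpeciesEntry, SpeciesInfo

__all__ = [
    "SPECIES_REGISTRY",
    "RESOURCES",
    "METABOLITES",
    "CORE_GENERA",
    "IN_SILICO_FRACTIONS",
    "build_group",
    "fixture_groups",
]

#: Chemical species registry: molar mass (g/mol) and kind.  Polymeric
#: resources use per-monomer masses (anhydroglucose 162.14 for starch/NSP,
#: a mean amino-acid residue of 110 for protein).
SPECIES_REGISTRY: dict[str, SpeciesInfo] = {
    "resistant_starch": SpeciesInfo(162.14, "resource"),
    "nsp": SpeciesInfo(162.14, "resource"),
    "protein": SpeciesInfo(110.0, "resource"),
    "sugars": SpeciesInfo(180.16, "resource"),
    "acetate": SpeciesInfo(60.05, "metabolite"),
    "propionate": SpeciesInfo(74.08, "metabolite"),
    "butyrate": SpeciesInfo(88.11, "metabolite"),
    "lactate": SpeciesInfo(90.08, "metabolite"),
    "formate": SpeciesInfo(46.03, "metabolite"),
    "succinate": SpeciesInfo(118.09, "metabolite"),
    "ethanol": SpeciesInfo(46.07, "metabolite"),
    "co2": SpeciesInfo(44.01, "metabolite"),
    "h2": SpeciesInfo(2.016, "metabolite"),
    "ch4": SpeciesInfo(16.04, "metabolite"),
    "isobutyrate": SpeciesInfo(88.11, "metabolite"),
    "isovalerate": SpeciesInfo(102.13, "metabolite"),
    "valerate": SpeciesInfo(102.13, "metabolite"),
    "water": SpeciesInfo(18.02, "water"),
}

RESOURCES = [k for k, v in SPECIES_REGISTRY.items() if v.kind == "resource"]
METABOLITES = [k for k, v in SPECIES_REGISTRY.items() if v.kind == "metabolite"]

#: The 16 modeled core genera (Pseudobutyrivibrio, Bacteroides and Sarcina
#: were absent from all samples and are not modeled).
CORE_GENERA = [
    "Prevotella",
    "Megasphaera",
    "RC9",
    "Streptococcus",
    "Lactobacillus",
    "Alloprevotella",
    "Clostridium",
    "Treponema",
    "Faecalibacterium",
    "Succinivibrio",
    "Blautia",
    "Phascolarctobacterium",
    "Ruminococcus",
    "Parabacteroides",
    "Escherichia",
    "Turicibacter",
]

#: Default initial relative abundances (%), the in-silico community column
#: of the published composition table (mean of the three bioreactors at T0).
IN_SILICO_FRACTIONS: dict[str, float] = {
    "Prevotella": 23.58,
    "Megasphaera": 13.20,
    "RC9": 2.93,
    "Streptococcus": 1.68,
    "Lactobacillus": 1.76,
    "Alloprevotella": 1.90,
    "Clostridium": 0.87,
    "Treponema": 0.73,
    "Faecalibacterium": 1.15,
    "Succinivibrio": 0.07,
    "Blautia": 0.24,
    "Phascolarctobacterium": 0.53,
    "Ruminococcus": 0.27,
    "Parabacteroides": 0.03,
    "Escherichia": 0.01,
    "Turicibacter": 0.04,
    "others": 51.00,
}


def _entry(name: str, rclass: str, n: float = 1.0, K: float | None = None,
           Y: float | None = None) -> tuple[str, SpeciesEntry]:
    m = SPECIES_REGISTRY[name].molar_mass
    return name, SpeciesEntry(rclass, m, n, half_sat=K, yield_=Y)


def _pw(pid: str, mu: float, entries: list[tuple[str, SpeciesEntry]]) -> PathwaySpec:
    return PathwaySpec(pid, mu, dict(entries))


# (mu_max 1/h, K g/L, Y g/g); Sub = substitutable, Ess = essential,
# Boost = boosting, W = water, P = product
def _sub(name, K, Y=0.333, n=1.0):
    return _entry(name, "substitutable", n, K, Y)


def _ess(name, K, Y=0.333, n=1.0):
    return _entry(name, "essential", n, K, Y)


def _boost(name, K, n=1.0):
    return _entry(name, "boosting", n, K)


def _w(n=1.0):
    return _entry("water", "water", n)


def _p(name, n=1.0):
    return _entry(name, "product", n)


def fixture_groups() -> dict[str, GroupSpec]:
    """Build the full synthetic 17-group parameter library."""
    g: dict[str, GroupSpec] = {}

    g["Prevotella"] = GroupSpec("Prevotella", [
        _pw("nsp_sugar_fermentation", 0.45, [
            _sub("nsp", 0.02), _sub("sugars", 0.03), _w(),
            _p("acetate", 2), _p("propionate", 1), _p("succinate", 1), _p("co2", 3),
        ]),
    ], (4.8, 5.6, 7.4, 8.3))

    g["Megasphaera"] = GroupSpec("Megasphaera", [
        _pw("lactate_utilization", 0.55, [
            _sub("lactate", 0.005, 0.25), _w(),
            _p("propionate", 1), _p("butyrate", 1.5), _p("co2", 2), _p("h2", 2),
        ]),
        _pw("sugar_fermentation", 0.25, [
            _sub("sugars", 0.05),
            _p("propionate", 1), _p("butyrate", 1), _p("co2", 1),
        ]),
    ], (4.6, 5.5, 7.5, 8.4))

    g["Succinivibrio"] = GroupSpec("Succinivibrio", [
        _pw("sugar_succinate_fermentation", 0.50, [
            _sub("sugars", 0.008), _w(),
            _p("acetate", 1), _p("succinate", 2), _p("formate", 1),
        ]),
    ], (5.0, 5.8, 7.6, 8.4))

    g["Blautia"] = GroupSpec("Blautia", [
        _pw("sugar_fermentation", 0.12, [
            _sub("sugars", 0.05),
            _p("acetate", 2), _p("ethanol", 1), _p("co2", 1),
        ]),
        _pw("homoacetogenesis", 0.50, [
            _ess("h2", 0.0002, 0.1, n=4), _ess("co2", 0.005, 0.3, n=2),
            _p("acetate", 1),
        ]),
    ], (4.7, 5.6, 7.5, 8.5))

    g["Ruminococcus"] = GroupSpec("Ruminococcus", [
        _pw("starch_degradation", 0.38, [
            _ess("resistant_starch", 0.02), _w(),
            _p("acetate", 0.3), _p("formate", 1), _p("ethanol", 1), _p("h2", 2),
            _p("succinate", 0.5), _p("co2", 3),
        ]),
    ], (5.2, 6.0, 7.2, 8.0))

    # --- fastidious genera: mu_max below the 0.111 1/h dilution rate -----

    g["RC9"] = GroupSpec("RC9", [
        _pw("nsp_fermentation", 0.09, [
            _sub("nsp", 0.05), _w(),
            _p("acetate", 1), _p("propionate", 1), _p("co2", 1),
        ]),
    ], (5.0, 5.9, 7.3, 8.2))

    g["Streptococcus"] = GroupSpec("Streptococcus", [
        _pw("homolactic_fermentation", 0.10, [
            _sub("sugars", 0.02),
            _p("lactate", 2),
        ]),
    ], (4.6, 5.4, 7.6, 8.6))

    g["Lactobacillus"] = GroupSpec("Lactobacillus", [
        _pw("heterolactic_fermentation", 0.095, [
            _sub("sugars", 0.015),
            _p("lactate", 1), _p("ethanol", 1), _p("co2", 1),
        ]),
    ], (3.8, 4.8, 6.9, 7.9))

    g["Alloprevotella"] = GroupSpec("Alloprevotella", [
        _pw("nsp_fermentation", 0.09, [
            _sub("nsp", 0.04), _w(),
            _p("acetate", 1), _p("succinate", 1),
        ]),
    ], (4.9, 5.7, 7.4, 8.3))

    g["Clostridium"] = GroupSpec("Clostridium", [
        _pw("proteolytic_fermentation", 0.08, [
            _ess("protein", 0.08, 0.25), _w(),
            _p("acetate", 1), _p("butyrate", 1), _p("h2", 2), _p("co2", 1),
        ]),
    ], (4.8, 5.6, 7.5, 8.5))

    g["Treponema"] = GroupSpec("Treponema", [
        _pw("nsp_fermentation", 0.085, [
            _sub("nsp", 0.06),
            _p("acetate", 2), _p("formate", 1),
        ]),
    ], (5.1, 5.9, 7.2, 8.1))

    g["Faecalibacterium"] = GroupSpec("Faecalibacterium", [
        # butyrogenesis from starch, enhanced by (but not consuming) acetate
        _pw("starch_butyrogenesis", 0.07, [
            _sub("resistant_starch", 0.03), _boost("acetate", 0.05), _w(),
            _p("butyrate", 1), _p("formate", 1), _p("h2", 1),
        ]),
    ], (5.0, 5.8, 7.0, 7.9))

    g["Phascolarctobacterium"] = GroupSpec("Phascolarctobacterium", [
        _pw("succinate_utilization", 0.09, [
            _sub("succinate", 0.005, 0.2),
            _p("propionate", 1), _p("co2", 1),
        ]),
    ], (5.0, 5.8, 7.4, 8.2))

    g["Parabacteroides"] = GroupSpec("Parabacteroides", [
        _pw("nsp_fermentation", 0.08, [
            _sub("nsp", 0.05),
            _p("acetate", 1), _p("propionate", 1), _p("succinate", 1),
        ]),
    ], (4.9, 5.8, 7.3, 8.3))

    g["Escherichia"] = GroupSpec("Escherichia", [
        _pw("mixed_acid_fermentation", 0.075, [
            _sub("sugars", 0.01),
            _p("acetate", 1), _p("ethanol", 1), _p("formate", 1),
            _p("h2", 1), _p("co2", 1),
        ]),
    ], (4.2, 5.0, 7.9, 8.8))

    g["Turicibacter"] = GroupSpec("Turicibacter", [
        _pw("homolactic_fermentation", 0.07, [
            _sub("sugars", 0.05),
            _p("lactate", 2),
        ]),
    ], (5.2, 6.0, 7.0, 7.8))

    # --- "others": the rest of the microbiota as 10 functional groups ----

    g["others"] = GroupSpec("others", [
        _pw("starch_degrader", 0.30, [
            _sub("resistant_starch", 0.3), _w(),
            _p("acetate", 1), _p("co2", 2),
        ]),
        _pw("nsp_degrader", 0.30, [
            _sub("nsp", 0.3), _w(),
            _p("acetate", 1), _p("propionate", 1), _p("co2", 2),
        ]),
        _pw("sugar_fermenter", 0.12, [
            _sub("sugars", 0.2),
            _p("acetate", 1), _p("ethanol", 1), _p("co2", 1),
        ]),
        _pw("proteolysis", 0.50, [
            _ess("protein", 0.05, 0.25), _w(),
            _p("propionate", 0.3), _p("butyrate", 0.5), _p("isobutyrate", 0.4),
            _p("isovalerate", 0.4), _p("valerate", 0.3), _p("h2", 2.5), _p("co2", 3),
        ]),
        _pw("lactate_producer", 0.20, [
            _sub("nsp", 0.1, 0.30), _w(),
            _p("lactate", 2),
        ]),
        _pw("lactate_utilizer", 0.10, [
            _sub("lactate", 0.05, 0.25),
            _p("propionate", 1), _p("acetate", 1),
        ]),
        _pw("methanogenesis", 0.06, [
            _ess("h2", 0.005, 0.1, n=4), _ess("co2", 0.01, 0.3, n=1),
            _p("ch4", 1),
        ]),
        _pw("succinate_utilizer", 0.30, [
            _sub("succinate", 0.01, 0.2),
            _p("propionate", 1), _p("co2", 2),
        ]),
        _pw("butyrate_producer", 0.15, [
            _sub("lactate", 0.08, 0.25), _sub("sugars", 0.3),
            _p("butyrate", 1), _p("co2", 1), _p("h2", 1),
        ]),
        _pw("formate_utilizer", 0.10, [
            _sub("formate", 0.02, 0.15),
            _p("co2", 1), _p("h2", 1),
        ]),
    ], (4.5, 5.5, 7.8, 8.8))

    return g


def build_group(name: str) -> GroupSpec:
    return fixture_groups()[name]
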