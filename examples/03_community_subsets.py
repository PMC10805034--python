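"""Compare the SCFA output of the full, core-only and others-only communities.

Three 35-day runs: (i) the 16 core genera plus "others" under
nearly-in-vivo conditions (two trait-perturbed strains per group and a
continuous microbial inflow, so every group persists), (ii) the core
genera alone, and (iii) the aggregated "others" group alone.  The spread
between (ii) and (iii) indicates how much of each metabolite the core
microbiota itself accounts for.
"""

import corechemostat as cc
from corechemostat.evaluation import gl_to_mM

for name in ("nearly_invivo", "cm_only", "others_only"):
    scenario = cc.build_scenario(name, seed=1)
    community = cc.builtin_community(scenario.metadata["community"])
    sim = cc.simulate(scenario, community)
    finals = {
        m: gl_to_mM(sim.species_trajectory(m)[-1],
                    community.registry[m].molar_mass)
        for m in ("acetate", "propionate", "butyrate", "lactate")
    }
    label = {"nearly_invivo": "core + others (nearly in vivo)",
             "cm_only": "core genera only",
             "others_only": "others only"}[name]
    print(f"{label:32s} " + "  ".join(
        f"{m} {v:6.1f} mM" for m, v in finals.items()))

print("\nButyrate depends heavily on 'others' (protein fermentation and "
      "lactate-fed butyrogenesis); the core genera alone skew toward "
      "acetate and propionate.")
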