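"""Simulate the 35-day bioreactor mimic and print the steady state.

The continuous fermenter runs at dilution rate 0.111 1/h (9 h retention)
on resistant starch, non-starch polysaccharides, protein and sugars.
Genera whose maximum growth rate falls below the dilution rate wash out;
the others settle into a steady state within ~10 days.
"""

import numpy as np

import corechemostat as cc
from corechemostat.evaluation import gl_to_mM, gl_to_pseudolog10

community = cc.builtin_community("bioreactor")
scenario = cc.build_scenario("bioreactor")
sim = cc.simulate(scenario, community)

print(f"Simulated {scenario.duration_h / 24:.0f} days, "
      f"{sim.microbes.shape[1] + sim.species.shape[1]} state variables\n")

print("Final genus abundances (pseudo-log10 bacteria/L; 0 = washed out):")
for name in sim.groups.columns:
    level = gl_to_pseudolog10(np.array([sim.group_trajectory(name)[-1]]))[0]
    status = "persists" if level > 0 else "washed out"
    print(f"  {name:22s} {level:6.2f}  {status}")

print("\nFinal metabolite concentrations (mM):")
for name in ("acetate", "propionate", "butyrate", "lactate"):
    mm = gl_to_mM(sim.species_trajectory(name)[-1],
                  community.registry[name].molar_mass)
    print(f"  {name:12s} {mm:7.2f}")
print("\nLactate stays below the 0.1 mM detection limit: produced by the "
      "lactic genera but cross-fed away by Megasphaera and 'others'.")
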