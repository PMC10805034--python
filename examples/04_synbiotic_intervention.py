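"""Simulate a synbiotic intervention and its effect on SCFA production.

The intervention combines probiotics (20x Lactobacillus at 2.73 g/L and
20x Faecalibacterium at 1.78 g/L, dosed continuously) with a prebiotic
(5x resistant starch, 21.6 g/L inflow).  The dosed lactic bacteria feed
the lactate -> butyrate cross-feeders, and the extra starch feeds the
starch-fermenting butyrogens, so all three major SCFAs rise relative to
the unboosted baseline.
"""

import corechemostat as cc
from corechemostat.evaluation import gl_to_mM

community = cc.builtin_community("bioreactor")
base = cc.build_scenario("bioreactor")
synbiotic = cc.apply_synbiotic(base)  # the default published boosts

base_sim = cc.simulate(base, community)
syn_sim = cc.simulate(synbiotic, community)

print(f"{'metabolite':12s} {'baseline mM':>12s} {'synbiotic mM':>13s} {'change':>8s}")
for m in ("acetate", "propionate", "butyrate", "lactate"):
    mass = community.registry[m].molar_mass
    b = gl_to_mM(base_sim.species_trajectory(m)[-1], mass)
    s = gl_to_mM(syn_sim.species_trajectory(m)[-1], mass)
    change = f"{100 * (s - b) / b:+.0f}%" if b > 0.1 else "-"
    print(f"{m:12s} {b:12.2f} {s:13.2f} {change:>8s}")

print("\nThe dosed Lactobacillus and Faecalibacterium persist (continuous "
      "inflow outweighs washout); lactate itself stays undetected because "
      "the cross-feeders consume it as fast as it is produced.")
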