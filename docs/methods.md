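# Methods

## Model structure

The community model is a chemostat: a well-mixed anaerobic vessel with
inflow and outflow at dilution rate `D` (default 0.111 h⁻¹, the
reciprocal of a 9 h proximal-colon retention time).  State variables are
concentrations in g/L: one per microbial strain, one per chemical
species.  The baseline community — 16 core genera plus an aggregated
"others" group, 4 resource pools, 13 metabolites — has 34 states.

Every microbial group is a set of pathways.  A pathway lists chemical
species with a class tag and per-entry parameters:

| class | tag | consumed? | parameters |
|---|---|---|---|
| essential | Sₑ | yes | m, n, K, Y |
| substitutable | S | yes | m, n, K, Y |
| water | S_w | via stoichiometry | m, n |
| boosting | S_b | no | m, n, K |
| product | P | produced | m, n |

with m the molar mass (g/mol), n the stoichiometric molecule count, K the
Monod half-saturation constant (g/L) and Y the biomass yield (g/g,
0 < Y ≤ 1).

## Kinetics

Pathway growth is Monod-type, modulated by a trapezoidal pH factor
λ ∈ [0,1] defined by four ascending pH corners (zero at or outside the
outer pair, one between the inner pair, linear in between):

* essential resources combine by the **minimum** of their Monod terms
  S/(K+S) (Liebig's law);
* substitutable resources contribute Monod terms **weighted by their
  share of the total substitutable substrate mass**; when all
  substitutable substrates are exactly zero the term is zero (no 0/0);
* each boosting resource multiplies the rate by 1 + S/(2(K+S)), a
  bounded enhancement (≤1.5× per booster) that equals exactly 1 when the
  booster is absent, so boosting can accelerate but never enable growth.

These combination rules are this package's own fully specified choices
for behaviour that multi-group gut models usually delegate to their
kinetics framework; they reproduce the standard qualitative behaviour
(limitation, substrate switching, stimulation) with the fewest
parameters.

## Uptake, water and mass conservation

Per pathway, total uptake satisfies U = μ/Y resource-wise: each driving
resource r receives a share of the uptake proportional to its
stoichiometric mass m·n times its kinetic activity (1 for essential
entries, the within-class kinetic share for substitutable entries), and
is consumed at U_r = w_r μ / Y_r.  Water uptake is slaved to the
pathway's stoichiometry: U_w = (m_w n_w / Σ_growth m n) · Σ_r U_r.
The production rate of product z is

    M_z = (m_z n_z / Σ_k m_k n_k) · (Σ_r U_r + U_w − μ)

so Σ_z M_z + μ = Σ_r U_r + U_w holds identically — biomass plus products
exactly balance uptake, per strain, at every state and pH.  Because
Y ≤ 1, the residual is provably nonnegative.  Water is normally an
implicit, unlimited resource; a simulation can optionally track it as a
state, in which case a closed (D = 0) system conserves total mass to
solver precision.

## Chemostat balances

    dB_j/dt = B_j (μ_j − D) + D B_in,j
    dC_s/dt = D (C_in,s − C_s) + Σ_j (M_js − U_js) B_j

A species may appear as a product of one group and a resource of another
(lactate, succinate, H₂, formate): cross-feeding needs no extra
machinery.  Washout is immediate from the balance: μ_max λ < D with no
inflow forces extinction; any positive microbial inflow guarantees
persistence at or above B_in.

## Scenarios

All presets run 35 days at pH 6.4 (midpoint of the experimental 6.0–6.8
band; a time-schedule is supported but the presets hold pH fixed) with
medium inflow resistant starch 4.32, NSP 7, protein 15, sugars 2 g/L,
initial metabolites 0 g/L, and initial resources equal to the medium.
Initial community biomass is 7.756 g/L (≈1.69·10¹² bacteria/L at
4.6·10⁻¹² g/cell) partitioned by the in-silico composition column of the
packaged abundance table; this total is fixed by back-computing the
published 20× probiotic doses (2.73 g/L *Lactobacillus*, 1.78 g/L
*Faecalibacterium*), which are mutually consistent only with that column.

* `bioreactor`: one strain per group, no microbial inflow (in vitro mimic).
* `nearly_invivo`: two strains per group at 10% trait variability plus a
  continuous microbial inflow at 10% of the initial concentrations (the
  study states that groups flow in continuously but not at what level;
  10% keeps every group present without dominating the dynamics).
* `cm_only` / `others_only`: bioreactor settings over reduced communities.
* `apply_synbiotic`: a boosted microbe's initial concentration is
  multiplied by the fold-change and the **excess over baseline** is dosed
  continuously (inflow += (fold−1)·baseline), so a fold-change of 1 is
  exactly the identity; a boosted resource scales its inflow
  concentration.  Defaults: 20× *Lactobacillus*, 20× *Faecalibacterium*,
  5× resistant starch (21.6 g/L).

The vessel volume (234 mL) never enters the concentration-based
equations and is kept as scenario metadata.

## Integration

`scipy.integrate.solve_ivp` with LSODA, rtol 1e-8, atol 1e-10 (presets),
hourly output grid.  Cross-feeding makes the system stiff; LSODA switches
to BDF automatically.  After integration, magnitudes below 1e-15 g/L are
clipped to zero; a state more negative than ~100·atol raises an
integration error advising tighter tolerances.  The kinetics kernel is a
single dense-array implementation shared by the per-strain rate functions
and the ODE right-hand side, so the tested algebra is the integrated
algebra.

## The packaged community is synthetic

The study parameterised each genus from culture data of representative
species in ~20 supplementary tables that are not redistributable.  The
packaged community is therefore a synthetic stand-in, designed (not
fitted to any acceptance outcome) to reproduce the documented qualitative
behaviour under the baseline conditions:

* *Prevotella*, *Megasphaera*, *Succinivibrio*, *Blautia*, *Ruminococcus*
  and "others" have μ_max·λ > D in their niche and persist; the remaining
  11 genera have μ_max < D (for the boosted *Faecalibacterium* pathway,
  μ_max·1.5 < D) and wash out;
* each persister owns one limiting substrate: NSP (*Prevotella*), sugars
  (*Succinivibrio*), resistant starch (*Ruminococcus*), lactate
  (*Megasphaera*), H₂ (*Blautia*, as homoacetogen), protein ("others"),
  so coexistence at steady state is structurally guaranteed rather than
  accidental;
* lactate producers (*Streptococcus*, *Lactobacillus*, *Turicibacter*,
  an "others" pathway) are balanced by high-affinity consumers
  (*Megasphaera* K = 0.005 g/L), keeping lactate below the 0.1 mM
  detection limit at all times;
* saccharolytic yields are 0.333 g/g; protein and lactate pathways use
  0.25, acetogenic/methanogenic H₂ yields 0.1; μ_max values lie in
  0.06–0.55 h⁻¹; product stoichiometries were set so the steady state
  lands near the observed acetate > propionate > butyrate pattern with
  the balance of mass leaving as CO₂, H₂, ethanol, formate and
  branched-chain fatty acids.
* "others" represents the non-core microbiota through 10 functional
  pathways (starch, NSP and sugar fermenters, proteolysis, lactate
  producer and utilizer, methanogen, succinate utilizer, butyrate
  producer, formate utilizer).
* the 13-metabolite list includes three protein-fermentation branched
  acids (isobutyrate, isovalerate, valerate) standing in for metabolites
  whose identities the main text does not list; names are configurable
  through the species registry.

Quantitative steady states of the original study are consequently **not**
reproduced, and no test asserts them; what the tests do pin down is the
arithmetic of the framework (conservation, closed forms, conversions),
the scenario definitions, and the qualitative fixture behaviour above.

## Evaluation and unit conversions

Metabolites convert to mM as (g/L·1000)/molar mass.  Microbes convert to
bacteria/L at 4.6·10⁻¹² g/cell and then to pseudo-log₁₀ with every value
at or below 1 bacterium/L mapped to 0.  Model output is linearly
interpolated (in g/L) onto the observation times; modeled and observed
metabolite values below 0.1 mM, and abundances below 1 bacterium/L,
report as 0, mimicking GC-MS/qPCR floors.  Per variable the comparison
reports RMSE, RMSE% = 100·RMSE/mean(obs) (missing when the mean is 0, as
for undetected lactate), and the two-sided slope p-value of an OLS
regression of modeled on observed values (no multiple-testing
correction, matching how such tables are conventionally presented).
The core-fraction summary computes each sample's core share as 100 minus
the non-core share, which is robust to the rounding of individually
printed per-genus percentages; the across-reactor SD is the sample (n−1)
standard deviation.

## Half-saturation calibration

`calibrate_K` formalises the study's empirical loop: every K starts at
the 0.001 g/L convention; the search cycles through the K coordinates,
drawing one log-uniform proposal at a time inside a window centred on the
current best value (the window initially spans the full bounds, default
[1e-4, 1] g/L, and shrinks by 0.85 per full pass down to 0.05 decades),
accepting only improvements in the summed per-variable RMSE.  Failures
score as infinite; the search is deterministic per seed, never leaves the
bounds, and its best score is non-increasing in the budget.

The recovery benchmark is a 3-group world (fiber degrader → lactate →
lactate utilizer → butyrate, plus a sugar fermenter) with true K of
0.08, 0.15 and 0.05 g/L, chosen large enough relative to the 5 g/L feed
concentrations that the observed transients are informative about K.
Problem sizes used throughout: 240 h benchmark simulations on a 2 h
grid, 22 observation times (dense early), budget 500 for noise-free
recovery and 120 per seed across 20 seeds for the noise-bias experiment.

## Synthetic observations

`generate_observations` samples a simulated truth on a dense-early /
sparse-late schedule (8 h, then days 1, 1.7, 3, 4, 5.5, 10, 15, 20, 25,
30, 35), applies multiplicative lognormal noise on bacteria/L (σ = 0.15,
≈0.065 log₁₀) and additive Gaussian noise on metabolite mM (σ = 2 mM),
then truncates below the detection limits.  It emulates only the derived
quantities the model is compared against — not reads, chromatograms or
amplification curves — so passing tests say nothing about upstream
measurement pipelines.  The packaged `bioreactor_observations()` series
is likewise synthetic: anchored point-wise to published summary numbers
(initial and steady SCFA levels, time-averaged genus abundances, lactate
undetected throughout, declining washout trajectories) with interpolated
values in between.

## Numerical choices and edge cases

* substitutable weighting with all substitutable substrates at 0 returns
  rate 0; pathways with zero growth take up and produce exactly nothing;
* strain-trait perturbation redraws inner pH corners until the ordering
  c₁ < c₂ ≤ c₃ < c₄ holds, so invalid strains are never emitted;
  variability 0 reproduces the parent bit-for-bit;
* group frames serialise with shortest-round-trip float formatting, so
  writing the same spec twice is byte-identical and read∘write is the
  identity;
* observation times must lie inside the simulated span; variables
  observed but absent from a simulation are reported as unmatched, never
  silently dropped.

## Known limitations

No spatial structure, host absorption, immune interaction or pH feedback
(pH is an input, not a state); yields are inputs rather than derived from
thermodynamics; the boosting rule and the uptake apportionment are
plausible but not mechanistically derived; the synthetic community
reproduces qualitative, not quantitative, study behaviour; strain
variability is uniform and independent across traits, with no
documentation of the real trait covariance.
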