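# Methods

## Model structure

The simulator is a stochastic cellular automaton on a bounded 2D square
lattice with Moore (Chebyshev) neighborhoods and absorbing borders (moves
are clipped at the edge; there is no wraparound). Positions are 0-based
integer (row, col) with origin top-left. Four agent kinds exist: tumor
cells and cytotoxic (N_C), exhausted (N_E) and vigilant (N_V) NK cells.
One tick is ΔT = 4 h — chosen to approximate a single NK–tumor
conjugation/attachment cycle — and a grid cell is l = 50 μm across with a
hard carrying capacity of BMax = 25 tumor cells per site. NK agents are
not capacity-limited; only tumor occupancy is.

Each step: (1) the activation order of all live agents is freshly
shuffled with the replicate's generator; (2) each agent moves and then
acts (N_C: one kill attempt against a uniformly random live tumor cell in
its own or Moore-1 sites, then death, then division; tumor: death, then
division, after movement); (3) phenotype transitions are resolved against
the end-of-step tumor field; (4) cytokine fields decay and receive
deposits; (5) dosing / re-challenge events due that tick are applied and
metrics recorded. Daughters are registered on the lattice immediately —
so capacity checks later in the same step see them — but act from the
next step. Chemotaxis and the proliferation stimulus read a
neighborhood-summed tumor field computed once at the start of the step; a
within-step stale read is accepted in exchange for an O(1) lookup.

## Rate and probability conventions

Parameters stated per day are converted over the step: death uses
p = 1 − e^(−rΔT), division uses p = e^(rΔT) − 1 (capped at 1), and death
is drawn before division. The expected per-step multiplication factor is
then exactly e^((r_div − r_death)ΔT), which is what makes the tumor-only
growth-rate recovery tests sharp: a log-linear fit of ln(mean population)
against time returns the configured rate difference up to sampling noise.

Both truncated normals in the model (baseline cytotoxicity
c_NK ~ truncN(μ_c, σ_c²) and the realized proliferation rate
p_C′ ~ truncN(p_c*(t), σ_pc²)) are truncated to [0, ∞), since both are
non-negative quantities, and sampled exactly by inverse-CDF. With σ = 0
the draw degenerates to max(μ, 0). σ_pc is not independently specified
anywhere; the default is 0.01·pc (same relative width as the σ_c = 0.01
default against μ_c ≈ 0.5), exposed in the configuration.

## Key parameters (defaults)

| parameter | meaning | default | unit |
|---|---|---|---|
| μ_c, σ_c | baseline cytotoxicity mean / SD | product-specific, 0.01 | – |
| γ | CAR effect exponent | 0.5 CAR / 1.0 NT | – |
| b | genetic-effect scaling in G_NK | 0.1 | – |
| S0 | initial serial-killing capacity | product-specific (default 5) | cells |
| pc, bpc | NK proliferation rate / age decay | product-specific | /day, /step |
| B50, c50 | Hill half-maxima (tumor, cytokine) | 25, 70 | cells, – |
| γ₁, γ₂ | Hill exponents | 0.2, 0.2 | – |
| δ | Hill regularizer | 1e-6 | – |
| IL-15 / IL-21 half-life | cytokine decay | 2.5 / 0.2 | h |
| pV, dV | vigilant proliferation / death | 1e-3, 1e-3 | /day |
| pE | exhausted proliferation | 0 | /day |
| kB−, kB+ | N_C→N_V, N_V→N_C probabilities | 1.0, 0.9 | – |
| pB | tumor proliferation | 0.455 lymphoma / 0.223 GBM | /day |
| dB, mB, vB | tumor death / move prob / speed | 1e-4, 0.1, 1 | /day, –, cell/step |
| p_mutate | mutation probability per division | 1e-3 | – |
| mN, vN | NK move probability / speed | 0.9, 39 | –, μm/h |
| ΔT, l, BMax | step, cell size, capacity | 4 h, 50 μm, 25 | |

## Design choices where the design was open

- **Cytokine production and transport.** Decay is specified by species
  half-lives, but production magnitude and spatial spread are not fixed
  by the biology we model. We use no diffusion; each armored NK agent
  deposits 1.0 (dimensionless) into its own site per step. Levels only
  enter through Hill ratios against c50, so the deposit sets an overall
  scale rather than a mechanism.
- **Hill-term parenthesization.** w = kB·(c^γ₂ + δ)/(c^γ₂ + c50^γ₂ + δ),
  which makes c50 the genuine half-maximum of the cytokine factor; δ =
  1e-6 keeps w nonzero with negligible (≈1e-6) displacement of the
  half-maximum, verified by the root-finding tests at δ → 0.
- **Autonomous-growth assays.** With no tumor present kB is pinned to a
  configured constant (default 1.0) so the cytokine effect remains active
  when fitting NK-only expansion data.
- **Capacity enforcement.** A division whose home site is full places the
  daughter in a uniformly random non-full Moore-1 neighbor, else the
  division is skipped that step; tumor moves into full sites are refused.
  BMax is thereby a hard invariant, stress-tested over 20 simulated days
  of saturated growth.
- **Clearance and recall.** "Local tumor clearance" means zero tumor
  cells within Moore radius 1 at end of step; N_V eligibility requires
  having been tumor-exposed. Recall restores s to S0 (preserved effector
  function) — an assumption, flagged as such.
- **Inheritance.** NK daughters inherit the mother's expression profile
  (copied, so later marker accumulation stays per-agent), c_NK, and
  *current* s; age resets to 0. Tumor daughters inherit antigen
  expression and mutation count, then mutate independently with p_mutate.
- **Exhaustion-marker updates.** Under EM2/EM3 each kill adds +1 to every
  flagged marker entry before s is recomputed, so with a single flagged
  marker at x50 = 1 the first kill gives γ_exh = 0.5 and
  s = S0 − e^0.5. x50 defaults to 1.0 per marker (no independent value
  exists); the default exhaustion variant is EM1, the simplest, with
  EM2/EM3 selectable per product.
- **Exhausted agents** are inert occupants: they neither kill nor
  stimulate, and die at rate dE regardless of antigen context.
- **Evasion.** p_evade = clip(p_base·(1 − κ·antigen) + mutations·1e-3,
  0, 1) with κ = 0.5 by default (the antigen scaling constant is
  otherwise unconstrained).
- **Initial placement.** Default `center`: tumor packed into the smallest
  central disk at capacity with NK on the surrounding annulus (the
  in-vivo layout). A `uniform` mode scatters tumor cells sparsely at
  random; it exists because a capacity-saturated disk grows from its
  surface (sub-exponentially), whereas sparse placement leaves the
  per-step division probability unconstrained so configured growth rates
  are identifiable. The growth-rate assays use `uniform`; spatial
  treatment simulations use `center`.
- **Dosing.** A dose event adds multiplier × (n_tumor_init · ETR)
  freshly sampled cytotoxic agents on the periphery annulus (or
  peritumorally, for intratumoral administration scenarios).
  Re-challenge mode adds configured tumor boluses on schedule.
- **Calibration search.** Exhaustive grid per stage with staged order
  (tumor rates → per-group NK parameters under each ETR candidate →
  linear refinement between the incumbent's grid neighbors, default one
  refinement stage splitting the bracket into 4), candidate screening at
  a reduced replicate count (default 5) with full-replicate re-evaluation
  of incumbents. Refinement merges candidate lists, so the refined best
  MSE can never exceed the coarse best. Stability is reported as the
  coefficient of variation of burden across replicates at each observed
  day.

## Random numbers and reproducibility

Each replicate r of a run with base seed s uses one
`numpy.random.Generator` seeded with s + r; every stochastic decision in
that replicate flows from it. Records are bit-identical across repeated
runs at the same seed (asserted in the suite).

## What the synthetic generators emulate — and what they do not

The fixture module stands in for data the model consumes but this package
does not produce: an upstream regression-coefficient table (synthetic ids
plus LAG3/PDCD1 flagged with strictly negative coefficients) and a
normalized expression pool (per-feature-scaled log-normal draws). These
reproduce the *interfaces* — aligned feature order, non-negative
normalized values, marker sign convention — but none of the count
structure, dropout, batch effects or pathway-density scoring of real
single-cell data. Tests passing on these fixtures therefore validate the
simulator's mechanics and plumbing, not any biological claim about a
particular gene program. Observed-progression fixtures are either
analytic exponential-ratio curves (fast unit tests) or generated by the
simulator itself at known parameters (the preferred closed-loop recovery
check for calibration).

## Problem sizes used in the shipped checks

Growth-rate recovery uses 1000 initial tumor cells on a 100×100 grid, 8
(lymphoma) or 10 (glioblastoma) simulated days, 30 replicates. Decay
recovery uses 12 steps of a uniform field. Transition frequencies use 100
(clearance) and 10×1000 (recall) agents; mutation frequency accumulates
≥10⁵ division events; the capacity stress test runs 20 days on a 60×60
grid (5 replicates in the acceptance script). Calibration recovery tests
run 150–300 tumor cells on 30×30 grids over ≤4 days — deliberately small,
scaled so the full suite stays interactive while every estimate keeps a
comfortable margin against its tolerance.

## Known limitations

No cytokine diffusion or pharmacokinetics, no 3D or multi-compartment
geometry, no metabolic competition or toxicity, no host immune cells
beyond the four agent types. Per-product fitted parameter values are not
shipped: product blocks default to illustrative values and are meant to
be calibrated against the user's own progression data. The genetic-effect
pipeline consumes coefficients; it does not fit the upstream
mixed-effects feature-selection model.
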