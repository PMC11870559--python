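# nkact

On-lattice agent-based simulation of natural-killer (NK) cell adoptive
cell therapy (ACT) against tumors, with simulation-based calibration and
in-silico trial utilities.

## The problem

Adoptive transfer of NK cells — non-transduced (NT), CAR-engineered
(e.g. anti-CD19), or cytokine-armored (IL-15 / IL-21 expressing) — shows
very different tumor control across products, and the cell-level causes
(cytotoxicity, serial-killing capacity, exhaustion, proliferation support)
are hard to disentangle from bulk tumor-burden curves alone. `nkact`
provides a mechanistic, cell-level model: tumor cells and three NK
phenotypes interact on a bounded 2D Moore lattice, and every hypothesized
cellular property is an explicit, perturbable parameter. The package is
aimed at computational immunologists and systems biologists who want to
fit such a model to tumor-progression data and run virtual dosing /
scheduling experiments.

## The model

Agents act stochastically each step (ΔT = 4 h, one NK–tumor conjugation
cycle; grid cell 50 μm, ≤ 25 tumor cells per site). Per-day rates r become
per-step probabilities 1 − e^(−rΔT) for death and e^(rΔT) − 1 for
division, so configured rates are recoverable from simulated growth
curves.

**Cytotoxic NK cells (N_C)** kill an adjacent tumor cell with

    p_kill = [1 / (1 + e^-(c_NK + G_NK))]^γ · (1 − p_evade)

where c_NK ~ truncN(μ_c, σ_c²) is baseline cytotoxicity, γ is the CAR
effect exponent (0.5 CAR / 1.0 NT), and G_NK = tanh(b·Σᵢ βᵢgᵢ) embeds a
per-agent expression profile g (sampled from a single-cell pool) weighted
by regression coefficients β of features associated with tumor control.
Each N_C carries a serial-killing capacity starting at S0; three
exhaustion variants deplete it (EM1: s = S0 − ΣI_kill; EM2: kills also
accumulate exhaustion-marker expression — LAG3, PDCD1 — degrading p_kill
through G_NK; EM3: s = S0 − ΣI_kill·e^γ_exh with
γ_exh = Σ x/(x50 + x)). At s = 0 the agent becomes **exhausted (N_E)**,
inert. After local tumor clearance, exposed N_C convert to **vigilant
(N_V)** with probability kB− = 1.0; on tumor re-exposure N_V recall to N_C
with probability kB+ = 0.9.

N_C proliferation is stimulated by local tumor load B and cytokine level
c through saturating Hill terms:

    pc*(t) = pc · exp(w − bpc·t),
    w = kB · (c^γ₂ + δ)/(c^γ₂ + c50^γ₂ + δ),
    kB = (B^γ₁ + δ)/(B^γ₁ + B50^γ₁ + δ)

with B50 = 25, c50 = 70, γ₁ = γ₂ = 0.2. Armored products deposit their
cytokine locally; fields decay with species half-lives (IL-15: 2.5 h,
IL-21: 0.2 h). **Tumor cells** divide (lymphoma 0.455/day, glioblastoma
0.223/day), die (1e-4/day), random-walk, acquire resistance mutations
with probability 1e-3 per division (raising p_evade), while high
CAR-target antigen expression lowers p_evade. NK agents chemotax toward
the highest local tumor concentration.

Calibration minimizes the mean squared error between simulated and
observed *normalized tumor progression* (treated burden / matched
tumor-only control burden) via a staged coarse-to-fine grid search: tumor
rates first, then per-group NK parameters under each candidate
effector-to-target ratio (ETR). Sensitivity analysis fits a random-forest
regressor to perturbation sweeps and reports mean-decrease-in-impurity
and permutation importances; groups are compared with two-tailed
Mann–Whitney U tests under Benjamini–Hochberg correction.

## Worked example

```python
from nkact import TumorNKModel

model = TumorNKModel.from_config("examples/lymphoma_nt.yaml")
res = model.simulate(seed=1, replicates=5)
print(res.summary().round(3))
ctl = model.simulate(seed=1, replicates=5, tumor_only=True)
print("normalized progression at d7, d14:",
      res.normalized_vs(ctl, [7.0, 14.0]).round(3))
```

prints

```
                             value
duration_days               14.000
final_tumor              24112.600
final_tumor_fold            24.113
final_NC                  7260.000
final_NE                   422.800
final_NV                     1.800
tumor_deaths_cytotoxic    3939.400
tumor_deaths_programmed     17.000
auc_fold_B                 134.247
time_to_clearance              NaN
replicates                   5.000
normalized progression at d7, d14: [0.943 0.927]
```

Reading: over 14 simulated days the lymphoma population grows 24-fold
despite ~3,900 NK-mediated kills (vs 17 programmed tumor deaths); the NK
pool expands to ~7,300 cytotoxic agents with ~420 exhausted and a handful
of vigilant cells, and the treated burden ends at 93% of the matched
tumor-only control — NT-NK cells at this illustrative parameterization
slow but do not control the tumor. `time_to_clearance` is NaN because the
tumor is never cleared. Calibration (`model.fit(SearchSpace(...))`) and
the CLI (`nkact run|control|sweep|calibrate|fixtures`) build on the same
objects; `nkact fixtures --out fixtures/` writes synthetic effect-table /
expression-pool / progression files so everything runs without external
data.

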