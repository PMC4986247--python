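# Methods

## Scope and model summary

`ddrsim` simulates the DNA-damage response (DDR) of single mammalian cells
(parameterised for the U2-OS osteosarcoma line) to ionizing radiation (IR)
and TNFα, and classifies each simulated cell as viable, arrested or
apoptotic.  The network couples four modules — ATM/MRN damage detection,
the p53/Mdm2 core, the NF-κB (IKK/IκB/A20) module, and the Wip1 phosphatase
with its regulators (miR-16, KSRP, CREB) — across three well-mixed
compartments (extracellular matrix, cytoplasm, nucleus).  Levels are
molecule counts per cell; time is seconds.

The simulation is hybrid in the Haseltine–Rawlings sense: protein and
transcript levels form the deterministic partition, advanced by
fixed-step RK4; gene allele switching, DSB appearance/repair and TNF
receptor flips form the stochastic partition, simulated by the direct
Gillespie method with propensities frozen over each deterministic step
window and events applied at their sampled sub-step times.

## Model structure and rate-law conventions

Every ODE term is one row of a declarative reaction table: mass action for
synthesis, degradation, binding and transport; Michaelis–Menten for
enzymatic (de)phosphorylation; transcription of the stochastically
switched genes proportional to the active allele count (0, 1 or 2).
Cross-compartment transport terms are flagged and appear with opposite
signs in source and destination, so shuttled mass is conserved exactly.

Choices made where the biology admits several standard forms:

- **Mdm2/MdmX** are merged into a single Mdm2 species with cytoplasmic,
  nuclear-active and multi-phosphorylated-inactive nuclear forms.  ATM
  phosphorylates nuclear Mdm2 into the inactive fast-degrading form and
  promotes nuclear import of cytoplasmic Mdm2; Wip1 reverses the nuclear
  phosphorylation.
- **DSB repair is repair-complex limited**: the repair propensity is
  `vmax·D/(km+D)` in the DSB count `D`.  At high damage loads clearance is
  zero-order, so the time the detector module stays on grows linearly with
  dose.  With first-order repair the clearance time grows only
  logarithmically in dose, which we could not reconcile with both the
  ~18 h Wip1 maximum after 10 Gy and the dose-graded loss of
  clonogenicity; the saturating form reproduces both.
- **ATM switch-off is Wip1-gated**: the constitutive phosphatase activity
  opposing ATM is modelled with fixed capacity (Michaelis form in active
  ATM, small half-saturation constant).  The resting state is therefore
  held firmly off, while after an IR pulse the large active-ATM pool
  decays in a near zero-order "shoulder" whose duration shrinks as Wip1
  accumulates.  This realises the switch-off role of Wip1 without making
  ATM bistable: fully bistable variants either self-ignited from
  background damage or never switched off.
- **Gene switching**: the Wip1 gene is activated by p53, CREB and NF-κB,
  with the NF-κB arm damped by Wip1 itself (factor K/(K+Wip1)); Chk2 gene
  activation is p53-proportional with a p53-dependent inhibition factor;
  the ATM gene follows CREB.  These arms are linear in their regulator,
  as their activation probabilities are described as proportional to the
  transcription factor.  The p21 and Bax genes (the fate readouts) use a
  saturating p53 dependence `q·p53ᵃ·K/(K+p53ᵃ)`: with linear activation
  the Wip1-knockdown genotype's higher and longer p53 signal shifted its
  survival curve by many Gray-equivalents, far beyond the observed
  factor-two clonogenicity difference; saturation compresses the genotype
  effect to the observed scale while leaving the dose dependence (carried
  by signal duration) intact.
- **Deterministic-partition transcription** (Mdm2, p53, IκB, A20) is a
  TF-proportional rate rather than a switched gene.  Gene switching is
  the dominant stochasticity source, but keeping the p53/Mdm2 oscillator
  core deterministic keeps population medians sharp, matching how the
  figures of record present medians over 1000 cells.

## Parameters

Parameter classes:

- **Measured half-lives** (`HALF_LIVES_H`): first-order degradation
  constants are `ln2/t½` with half-lives in the 0.5–19 h range typical of
  chase (cycloheximide/actinomycin D) experiments; `fit_half_life`
  implements the corresponding log-linear regression estimator.
- **Synthesis limits**: transcription (≤ 0.02 mRNA/s per active allele)
  and translation (≤ 0.1 protein per mRNA per s) respect typical
  mammalian upper limits.
- **Structural constants**: compartment pool sizes (receptor pool 200,
  NF-κB total ~6·10⁴, ATM total ~3·10⁴), Michaelis constants ~10⁴
  molecules.
- **Fitted parameters** (`ModelSpec.fitted`): DSB yield/repair, the
  ATM→p53 and Wip1-deactivation rates, gene-switching weights for Wip1,
  p21 and Bax, and the NF-κB couplings.  These were adjusted by
  trial-and-error against the training landmarks: Wip1 mRNA maximum ~2 h
  and protein maximum ~18 h after 10 Gy; ~4-fold Wip1 reduction in the
  knockdown; the maximal active-p53 genotype difference ~2 h after IR;
  dose-graded apoptotic fractions and clonogenic survival with a
  factor-two genotype ratio at 2 and 4 Gy.  No uniqueness claim is made
  for this parameter set.

DSB induction is 35 DSB/Gy (γ-H2AX-scale yields) delivered at the
protocol dose rate (default 1 Gy/min), plus a spontaneous background
(~1 break per ~13 h) that produces the occasional late Wip1 activation
seen in unirradiated controls.

## Knockdown model

shRNA knockdown adds a first-order degradation term on the target mRNA.
Because Wip1 mRNA turnover is state-dependent (miR-16 rises after IR),
the added rate is calibrated iteratively against the resting state until
the resting protein equals `factor` × wild type (default 0.25).  The
response-phase fold is then close to, but not exactly, the resting fold;
keeping the miR-16 share of Wip1 mRNA turnover modest keeps both within
the tolerance used in the tests.

## Fate decision

Lower threshold: cell-cycle arrest while p21 ≥ `p21_arrest`.  Higher
threshold: apoptosis at the first instant active p53 AND Bax
simultaneously exceed their thresholds.  Viability (colony formation):
a cell is not viable if it apoptoses before its first division or its
total arrest time exceeds 63.9 h.  The model has no cell-cycle clock, so
the first division occurs after 27 h of accumulated non-arrested time
(arrest pauses the cycle).  Arrest intervals are summed without requiring
contiguity; windows for apoptotic fractions are half-open `(lo, hi]`
anchored at irradiation.  Threshold values are configuration
(`FateThresholds`); the defaults (p21 9 500, active p53 6 500,
Bax 19 000 molecules) were calibrated on a 300-cell-per-condition
training grid spanning both genotypes, 0–10 Gy and the TNFα timing
protocols, jointly targeting the published clonogenic genotype ratios,
apoptotic fractions and untreated viability.  Threshold selection on
smaller calibration populations proved unreliable (selected optima
regressed on independent seeds), hence the grid size.

## Numerics

- Reference cadence follows the hybrid scheme's published settings
  (dt = 0.1 s, save every 10 s); population studies in this package use a
  relaxed step (dt = 2–4 s, saves every 5–10 min), validated by a
  step-halving test on the deterministic partition (< 0.5 % sup-norm
  change).  All first-order rates are ≤ 0.02 s⁻¹, so RK4 at dt = 4 s is
  far inside its stability region.
- Propensities are frozen over each step window; events are applied at
  their sampled sub-step time; windows never cross protocol
  discontinuities (IR start/stop, TNF washout).
- Negative-value guard: deterministic steps clip at 0 with a counter
  (`clip_count` in trajectory metadata).
- The per-cell RNG is a splitmix64 stream keyed by a seed derived from
  `(master_seed, cell_index)` via `numpy.random.SeedSequence`, so
  population results are independent of execution order.
- Population quantiles use the nearest-rank method for bit-stable
  results across platforms.
- The unstressed fixed point is located by relaxing the mean-field system
  (gene states and DSB count treated as continuous means) and polishing
  with a root finder; the mean-field right-hand side is also the
  deterministic-limit oracle in the tests.

## Synthetic data and what the tests show

The toy fixtures (birth–death process on the discrete counter, two-allele
gene toggle, exponential decay series) have closed-form stationary laws
and exercise the engine and estimators independently of the DDR model.
The time-compressed model variant (all rates ×60) preserves network
structure but not quantitative biology; it is used only for
population-level property tests (dose monotonicity, genotype ordering).
Passing tests therefore validate the numerical machinery and the model's
agreement with the published summary landmarks — they do not certify
predictive accuracy for other cell lines, damaging agents or dose rates,
and the cell-cycle phase dependence of the response is deliberately out
of scope.

## Known limitations

- Apoptosis in this calibration happens predominantly in the first day
  after irradiation: the joint p53/Bax condition is met while the damage
  response is still on, or during spontaneous re-ignition pulses whose
  active-p53 amplitude is capped by the Wip1-independent deactivation
  floor.  The published experiments place most 4 Gy + TNFα deaths in the
  second day; this model reproduces the first-day fraction and the total
  scale but under-produces the 24–48 h window (~0.3 % vs ~4.5 %).
  Attempts to raise late-pulse amplitudes past the apoptosis threshold
  made the Wip1-knockdown population (which is always in the low-Wip1
  state that gates those pulses) almost entirely apoptotic, destroying
  the clonogenic ratios, so the earlier-death compromise was kept.
- Because the 4 Gy apoptotic fraction is a ~1 % threshold-crossing tail,
  it is knife-edge sensitive to the Bax gene activation weight (+20 %
  moves it by ~3 percentage points); all other fitted parameters leave
  the fate outputs within Monte-Carlo noise, and viability is robust
  throughout.
- p53 shows a strong first pulse followed by a low sustained phase
  rather than repeated large-amplitude oscillations; population medians
  of the figures of record are matched, single-cell pulse trains are
  not a calibration target.
- Clonogenic survival of the wild type declines more gently with dose
  than the published assay (which loses essentially all colonies above
  6 Gy); dose-monotonicity and the genotype ordering are reproduced.

## Problem sizes

Test-suite and acceptance runs use populations of 100–200 cells (500 for
clonogenic ratios split across genotypes), horizons of 48–120 h and the
relaxed integration cadence; these sizes keep the full suite at desk
scale while leaving binomial error bars comfortably inside the stated
tolerances.  The library itself runs the full 1000-cell, 951 000 s
protocol when asked.
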