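# Methods

## The delayed SSA and its specialization

`txnsim.engine` implements the delayed stochastic simulation algorithm in
full generality: reactions carry instantaneous products plus any number of
delayed products, each with its own delay distribution (constant, Gaussian
redrawn until positive, or exponential); pending releases live in a
time-ordered waitlist (FIFO on ties). Each iteration draws a candidate SSA
step and compares it with the earliest release; the release wins ties. The
candidate discarded when a release wins introduces no bias because
exponential clocks are memoryless.

The transcription model itself runs on `txnsim._core`, the same algorithm
specialized to the template: every RNAP is a record (position, kinetic
phase, misincorporation flag, long-pause bookkeeping) rather than a set of
per-nucleotide species counts. The two views are equivalent — RNAPs cannot
pass each other — but the tracker makes per-molecule state direct and keeps
propensity updates local to the fired RNAP and its two neighbours, which is
what makes multi-hour trajectories of a 2445-nt template affordable in
pure Python (~2×10⁵ events/s). A cross-check test runs a birth–death system
with delayed products through both implementations and compares their
stationary laws.

## Kinetic scheme and conventions

Positions are 1-based; an RNAP at position *n* covers nucleotides
[*n* − Δ, *n* + Δ], Δ = 12. Moving requires nucleotide *n* + Δ + 1 free;
elongation starts on nucleotide 1 only when the first Δ + 1 = 13
nucleotides are free. The first α = 10 nucleotides activate at the slower
`k_act_first` = 30 s⁻¹ (abortive-phase elongation initiation); transcript
release from the activated last nucleotide occurs at `k_f` = 2 s⁻¹.

Decisions taken where the kinetics were open:

* **Residence hazards.** Pause, arrest, misincorporation,
  pyrophosphorolysis and premature-termination hazards act during the whole
  residence at a nucleotide (both the occupied and the activated
  sub-state). This is the only reading consistent with the published
  arithmetic — 0.55 s⁻¹ against a 75 nt/s dwell gives one pause per ~136
  activation events; attaching the hazard to a single sub-state would give
  ~273.
* **Pause exit.** Spontaneous exit is a first-order channel at rate
  1/`d_pause` — statistically identical to drawing an exponential duration,
  but it lets a collision end the pause early without cancelling a
  scheduled release. A paused RNAP resumes in the sub-state it paused from.
  `d_pause = 0` disables pause entry (zero-duration pauses are no-ops).
* **Collisions.** Each (activated trailing, paused leader)
  footprint-adjacent pair carries a collision channel with propensity
  `k_move` (the natural rate of the blocked move). The outcome is
  Bernoulli: leader released with probability 0.8, trailing paused too with
  probability 0.2. Collisions also truncate long-pause-site pauses; this is
  what produces the ~80 s secondary interval peak (one ~40 s headway plus a
  pause cut short by the follower's arrival).
* **Pyrophosphorolysis** steps the RNAP back one nucleotide into the
  occupied sub-state (the re-traversed nucleotide must be re-activated) and
  is blocked when the backward footprint is occupied or at nucleotide 1.
* **Editing** fires only on a misincorporation-flagged RNAP
  (`k_error_correct`), halting it for `d_correct` = 5 s and clearing the
  flag; arrest halts for `d_arrest` = 100 s and resumes the previous
  sub-state.
* **Initiation reservoir.** `n_rnap` = 28 polymerases are available for
  initiation *at all times*: the initiation propensity is
  `k_init · n_rnap` whenever the promoter is free, and terminating RNAPs
  leave the system. A conserved closed pool would throttle initiation
  whenever the template is congested and would break both the 42.4 s
  closed-form interval and the invariance of the completion rate to pausing
  kinetics; the reservoir reading preserves them.
* **Long-pause sites** are positional Bernoulli draws on first arrival
  (default once per RNAP), with an exponential duration and an optional
  premature-termination probability applied when the pause ends
  (spontaneously or by collision).

## Expression and degradation calibration

Translation is a multi-delayed reaction: a free RNA and free ribosome react
at `k_tr` = 0.00042 s⁻¹; the RNA returns after τ₁ = 2 s, the ribosome after
τ₂ = 56 s, the protein appears after τ₃ ~ N(420 s, 140 s). Species in the
waitlist are protected from degradation, which acts on free RNA and free
protein only.

The published degradation constants are mutually inconsistent with the
published calibration goals: at one completion per ~42.4 s, a mean of ~5
transcripts requires `deg_R` ≈ 0.0047 s⁻¹, not the printed 0.1 s⁻¹, and the
printed "~1.2 RNAs available" is not reachable from the other printed
rates. The package therefore treats degradation as a calibrated quantity:
`calibrate_degradation` sets `deg_R = production/target_R` (production
corrected by the premature-termination survival fraction) and
`deg_P = k_tr · n_rib · ⟨R_free⟩ / target_P`. The printed values are kept
as a preset (`PRINTED_DEGRADATION`). The protein balance deliberately
ignores ribosome sequestration (each translation holds a ribosome for
τ₂ = 56 s, ~12% of the pool at default rates), so realized protein means
run ~10% below target; stationary-level checks use a ±20% band for this
reason.

The repressilator couples three identical genes in a repression ring
(gene *i* repressed by protein *i* − 1): monomeric binding at
`k_r` = 0.1 s⁻¹ fully blocks initiation, unbinding at `k_u` = 10⁻⁴ s⁻¹,
bound-protein degradation at `k_dp` = 0.01 s⁻¹ frees the promoter, and free
repressors degrade at `deg_p_r` = 0.01 s⁻¹ (replacing the single-gene
`deg_P`). A promoter whose RNAP is in the open-complex stage is physically
occupied and cannot bind a repressor; already-elongating RNAPs finish after
repression. Network defaults inherit the *printed* RNA degradation rate (0.1 s⁻¹),
the oscillator's published operating point, while single-gene studies
default to the calibrated value.

## Analysis choices

* Microbursts are computed from exact completion event times (the sampled
  count series is available through the CLI for parity, but event times are
  exact in the simulator). An episode is a maximal run of completions with
  all successive gaps under the 5 s window and at least two members; the
  window must stay below the ~40 s open-complex delay.
* 2-means binarization initializes Lloyd iterations at (min, max), so it is
  deterministic and invariant to positive affine rescaling.
* The 3-tuple entropy uses natural log: a clean three-phase oscillator
  occupies ~3–4 of the 8 joint states, giving values near ln 3 ≈ 1.1–1.3,
  which is the scale of the published number; log₂ would not be.
* The period estimator smooths with a 5-sample moving average (500 s at the
  100 s sampling used for the repressilator — below a quarter period) and
  averages the intervals between successive upward midrange crossings,
  averaged over the three proteins.

## What the simulations do and do not show

All inputs are parameter configurations; there is no external data. The
synthetic scenarios (toy genes, the 400-nt long-pause cases A/B/C, the
repressilator) emulate the study conditions: fixed RNAP/ribosome
availability, a sequence-agnostic template with positional pause sites, no
backtracking, no codon-resolution translation, no post-translational
regulation, and a constant cell volume with no growth or division. Passing
tests therefore validate the kinetic scheme and its statistics, not
biological generality.

Problem sizes were chosen for single-CPU runtimes: stationary means use 3
cells × 20,000 s (burn-in 4,000 s); noise comparisons 5 cells × 20,000 s
per condition; the repressilator one 100,000 s trajectory sampled every
100 s; the empty-template transient 50 cells; long-pause cases 3 cells ×
20,000 s each. Closed-form checks are instantaneous.

Known limitations, measured honestly rather than tuned around:

* At `d_pause` = 100 s the promoter entry region congests (queues behind
  paused RNAPs reach the first 13 nucleotides), cutting the completion rate
  by ~40% — steric physics of the stated model that contradicts the claim
  that mean levels are independent of pause kinetics; the RNA-noise
  response at extreme `d_pause` therefore exceeds the published rise, and
  at extreme `k_pause` falls short of it.
* No parameterization consistent with the published tables reproduces the
  reported repressilator period (~7,000 s) and entropy (~1.2)
  simultaneously; measured values are ~4,500–6,000 s and ~1.06 with the
  printed degradation preset.
* The mean first completion from an empty template is ~128 s; the
  published "~150 s" describes the longer transient of the steady-state
  RNAP flow.
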