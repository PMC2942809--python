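# Methods

## Scope and assumptions

The package models the biochemistry of one serotonergic terminal as a
well-mixed, nine-species kinetic system. The extracellular compartment is
the share of extracellular space served by this terminal; diffusion
gradients ("hot spots" during burst firing) are ignored. The vesicular and
cytosolic compartments are taken to have equal volume — harmless here
because the model is not concerned with vesicle trafficking, only with the
partitioning of serotonin mass. The soma is not represented; somatodendritic
(5-HT1A) effects act only through the firing-rate driver `fire(t)`.
Deliberately excluded: vesicle creation/movement/recycling, SERT-mediated
leak of cytosolic 5-HT to the extracellular space, autoreceptor modulation
of reuptake, receptor desensitization dynamics, and competition of
tryptophan with other neutral amino acids at the blood–brain transporter.

Units are μM and hours everywhere in the core; extracellular 5-HT is
reported in nM at the presentation layer (baseline 0.768 nM = 0.000768 μM)
because its physiological range sits three orders of magnitude below the
other species.

## Parameters

Km values are literature-anchored and never touched: AADC 160, SERT 0.17,
MAT 0.198, TPH 40 (trp) and 20 (bh4) with substrate-inhibition constant
1000, combined MAO/ALDH 95, tryptophan transport 330 (effective, in the
presence of competing amino acids). Vmax values: AADC 400, SERT 4700
(middle of the measured regional range 2052–6480 μM/hr; regional variation
of SERT density by ~5× is exactly what the sweep experiments explore), MAT
3500, TPH 400, tryptophan transport 700 μM/hr (chosen so uptake at the
fasted serum level of 96 μM is ≈158 μM/hr). First-order constants: 5-HIAA
clearance 1/hr, removal of extracellular 5-HT by glia/blood/diffusion
k_rem = 400/hr.

NADPH and NADP are held as fixed cofactor levels (300 μM each) rather than
state variables; only their Km values are physiologically constrained, and
the choice moves nothing but the calibrated bh2\* (documented coupling,
covered by a test).

Autoreceptor constants: the synthesis factor is
`1.5 − e²/(e*² + e²)` with e\* = 0.768 nM; the release factor descends
linearly 1.5 → 1.0 over [0, e\*], then 1.0 → 0.4 over [e\*, 2.3 nM], constant
beyond. Both are exactly 1 at the operating point, so the resting state is
identical with feedback on or off — the property that makes the
homeostasis comparisons clean. A terminal 5-HT1B knockout pins both factors
at 1.

## Calibration

Three constants are under-determined by the physiology and are derived from
flux balance at the reference resting state (fire = 1/hr, fluox = 1,
btrp = 96 μM; cellular trp 20.6 μM, synthesis flux 5.57 μM/hr, e5ht
0.768 nM, trp-pool = 10 × trp):

* **Biopterin.** bh4\* solves V_TPH(trp\*, bh4, e\*) = 5.57 (bracketed root
  find; 0.8605 μM), bh2\* solves V_DRR(bh2, bh4\*) = 5.57 (0.1442 μM); their
  sum, 1.0047 μM, is the conserved biopterin pool.
* **Vesicular leak.** The resting extracellular balance forces
  v5ht\* = V_SERT + V_catab + V_rem = 21.453 μM, and catabolism closure
  forces c5ht\* = 0.5018 μM; `k_out = (V_MAT,uptake − v5ht*)/v5ht*` =
  115.99/hr then closes the vesicular balance. (The alternative consistent
  pair mat_vmax = 1226 with k_out = 40 is available by overriding mat_vmax;
  both reproduce the same resting state.)
* **Tryptophan pool.** With k₋₁ fixed at 0.6/hr, the pool must absorb
  uptake − synthesis = 152.18 μM/hr, giving k_catab = 0.7387/hr and
  k₁ = 13.387/hr. The nominal first-order constants k₁ = 6, k_catab = 0.2
  are *flux-infeasible*: the largest steady efflux k₁·trp\* = 123.6 μM/hr
  falls short of the required 152.2 μM/hr. Calibration logs this arithmetic
  as a warning instead of silently patching it, and a test pins the numbers.

The calibrated state is an exact fixed point of the equations (rhs residual
≈ 2e-13 μM/hr), and `calibrate()` is idempotent; the calibrated constants
ship as the frozen `KineticParameters` defaults.

One internal inconsistency of the reference values is worth noting: the
resting 5-HIAA implied by flux closure is 5.26 μM (total catabolic flux
5.263 μM/hr over a 1/hr clearance), whereas the quoted resting value is
5.22 μM — the reference numbers themselves disagree at the 1% level, and
the package reports the flux-consistent value.

## Numerics

* **Steady states** are found by a hybrid-Powell root find on the *reduced*
  eight-dimensional system with the biopterin total pinned to the seed's
  value — the full nine-dimensional Jacobian is structurally singular
  because bh2 + bh4 is conserved. Convergence demands ‖rhs‖∞ < 1e-8 μM/hr,
  far below the smallest flux of interest (extracellular catabolism
  ≈ 0.008 μM/hr). Failed or negative roots re-seed from a long integration
  (t = 10⁴ hr), which is reliable because the fixed point is locally stable
  (checked by finite-difference Jacobian eigenvalues). Sweeps use
  continuation: each solve is seeded from the neighboring solution.
* **Integration** uses LSODA with rtol 1e-8 / atol 1e-12 and a hard restart
  at every declared driver breakpoint (pulse edges, dose time, meal knots),
  so sub-second events never depend on step-size heuristics. Segments
  shorter than 36 s get a capped step (segment/60), guaranteeing a 0.2-s
  pulse is resolved by ≥ 50 accepted steps. Negative concentrations from
  round-off are clipped to zero only inside rate evaluation, never in the
  stored state, so conservation diagnostics stay honest.
* **Half-life** of a pulse excursion is defined on the *elevation above the
  pre-pulse baseline*, measured on the dense solution (peak refinement plus
  bracketed root find). Absolute half-life is ill-defined here because the
  decay is saturated-linear, not exponential, while extracellular 5-HT is
  far above the SERT Km.

## Experiment design choices

* **Pulse.** The SERT blockade in the fluoxetine variant is applied
  *acutely* from the wild-type resting state: a bath application on the
  seconds time scale blocks reuptake but does not re-equilibrate the
  vesicular store. This is also the only protocol under which the blocked
  peak comes out slightly *higher* than the unblocked one, as observed;
  pre-equilibrating at half-block would lower the vesicular store to
  19.9 μM and the peak with it.
* **Pulse half-lives.** With the stated SERT capacity, saturated reuptake
  clears 4700 μM/hr ≈ 1.31 μM/s and removal adds ≈ 0.22 μM/s at 2 μM, so
  the ~2 μM excursion halves in ≈ 0.76 s unblocked and ≈ 1.39 s at
  half-block (ratio ≈ 1.8 — the blockade roughly doubles the decay time).
  These are the package's numbers; commonly quoted experimental half-lives
  of ≈ 1 s and ≈ 2 s would require a smaller clearance capacity than the
  parameters above imply.
* **Meals.** Serum tryptophan is the fasted 96 μM plus one raised-cosine
  bump per meal (starts 07:00, 12:00, 18:00; 3 h rise, back to baseline 6 h
  after the start), doubling at the peak by default (plasma amino acids
  typically swing 2–4×; `peak_factor` is a first-class knob). Meals drive
  serum tryptophan only.
* **SSRI dosing.** The unblocked fraction follows
  `1 − 0.95·s²/(2.04 + s²)·e^(−s/37)` (s = hours since the 1-hr dose):
  blockade develops over ~1–2 hr, bottoms out at 0.232 unblocked 5.2 hr
  after the dose, and washes out with a 37-hr constant (a drug half-life of
  a little over a day, as for fluoxetine).
* **Firing suppression.** Raphe 5-HT1A stimulation is modeled by scaling
  `fire(t)` down in proportion to an occupancy-shaped curve, reaching the
  region-specific floor at peak occupancy: 58% of tonic for the median
  raphe → hippocampus pathway, 20% for the dorsal raphe → frontal cortex
  pathway (these floors map to steady extracellular 5-HT of ≈70% and ≈30%
  of baseline respectively). For the *agonist* experiment the occupancy
  washes out in 2 hr. For the *SSRI* experiment the suppression recovers
  with a 10-hr constant — faster than the drug — reflecting desensitization
  of the somatic 5-HT1A response under sustained exposure. This choice is
  forced by a steady-state argument: if firing stayed at 20% for as long as
  the SERTs stayed blocked, frontal-cortex extracellular 5-HT could never
  exceed ~90% of baseline at any blockade depth, whereas acute-dose
  microdialysis uniformly shows a rise in projection regions. The absolute
  peak percentages therefore inherit this timescale choice (flagged in each
  result's metadata); the *orderings* — hippocampus > frontal cortex,
  1B-knockout > wild type — are robust to it and are what the tests assert.

## What the tests do and do not show

The suite checks internal structure (conservation, flux closure,
rate-law monotonicity, independent re-derivation of the right-hand side),
solver quality (root-find vs long-integration agreement to 0.1%,
tolerance-convergence of pulse peaks), and the quantitative operating
points above. All of it concerns the model: agreement with the printed
reference state does not validate the model against new experimental data,
and regional heterogeneity (SERT density, autoreceptor expression) means
"the" terminal simulated here is one representative operating point, not a
universal one.

## Known limitations

Single terminal, single extracellular pool — no volume transmission between
terminals, no soma, no burst-firing statistics. The trp-pool is a lumped
two-way reservoir with first-order turnover, not a model of protein
turnover. SSRI action is a fixed pharmacodynamic curve, not
pharmacokinetics; receptor desensitization enters only through the firing
driver's washout constant. The 5-HIAA pathway is a single combined MM step
with first-order clearance, adequate for mass bookkeeping only.
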