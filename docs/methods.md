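# Methods

`hslpattern` simulates and analyzes a two-layer synthetic patterning circuit
in *E. coli*: two quorum-sensing signals (3OC6HSL sensed through LuxR at
P_Lux76\*, 3OC12HSL through LasR at P_Las81\*) each induce one fragment of a
split bacteriophage T7 RNA polymerase, so that transcription from a T7
promoter — read out as mRFP1 — occurs only where the two signals coincide.
CFP (mTurquoise2) and YFP (mVenus) mark the two input branches. The package
contains the synthetic-data generator for this circuit plus the full analysis
pipeline used to characterize it. This note records the model, the defaults,
and the reasoning behind the open design choices.

## Well model (circuitsim)

No kinetic rate laws are published for this circuit, so the generator uses
the simplest deterministic per-cell ODE model consistent with the observed
behaviors:

- **Promoter inputs.** Every inducible promoter follows a Hill law
  `basal + vmax * c^n / (K^n + c^n)`. Defaults: P_lac (IPTG) K = 0.2 mM,
  P_BAD (arabinose) K = 0.3 mM for the intact wild-type enzyme, n = 1.5
  throughout; P_Lux76\* K = 1 µM, P_Las81\* K = 0.5 µM. The R632S mutant and
  split variants carry a 30-fold higher arabinose half-activation constant
  (9 mM), the SynZIP-fused variants 110-fold (33 mM), encoding the reported
  shifts in half-maximal inducer. The basal-activity-reducing mutations in
  the hybrid promoters are modeled as zero promoter leak; residual background
  is carried by the T7 promoter's own basal rate, which keeps the AND null
  exact.
- **Species.** Per-cell concentrations of the T7RNAP protein (or its two
  fragments), LuxI/LasI synthase where present, and an immature/mature pair
  per fluorophore. Dilution is growth rate plus a first-order turnover
  (`deg = 0.004 /min`); maturation is first order (mTurquoise2 30 min,
  mVenus 15 min, mRFP1 60 min time constants).
- **Split complementation.** Active polymerase is the saturable bilinear
  form `vcat * nf/(K+nf) * cf/(K+cf)` (`split_K = 600` expression units):
  exactly zero when either fragment is absent (exact AND null), far from
  saturation at circuit expression levels so titration conditions remain
  well separated. Intact variants contribute activity linearly
  (`vcat * enzyme`).
- **Toxicity (burden).** High T7RNAP expression is toxic. The load is the
  (condition-wise constant) T7RNAP synthesis drive; above `burden_threshold`
  the penalty `1/(1 + slope*(load - threshold))` multiplies T7-catalysed
  synthesis, and growth is slowed by the same factor floored at
  `burden_growth_floor = 0.5` (toxicity at most halves growth in the
  simulated regime, so cultures still leave lag and reach the detector's OD
  floor). Only the intact wild-type set crosses the threshold inside the
  tested arabinose range (`threshold = 0.9` on the 0–1 drive scale,
  `slope = 40`), reproducing the decline of relative promoter activity above
  ~1 mM arabinose while all other variants stay monotone.
- **Resource competition.** T7-driven transcription out-competes host-driven
  expression: CFP and YFP synthesis are multiplied by
  `1/(1 + phi * t7_flux)`. `phi` is calibrated (below). In the ratiometric
  parameter sets `phi = 0`: the YFP/CFP ratio is designed to cancel shared
  capacity effects, so competition is modeled only where readouts are
  absolute intensities (the AND-gate sets).
- **Crosstalk.** P_Las81\* is weakly activated by 3OC6HSL
  (`crosstalk_eps = 0.03`, probabilistic-OR combination with its cognate
  input). All other promoter/signal pairs are orthogonal.
- **Growth and observation.** Logistic growth (r = 0.015 /min, K = 0.8
  OD600, inoculum 2×10⁻⁴ OD; cells start at their uninduced
  exponential-phase steady state). Observables are OD600 and per-channel
  fluorescence `gain * mature_fluorophore * OD + blank`, sampled every
  12 min for 100 cycles. Noise enters only at observation: per-channel
  log-normal CV (default 5%; OD 1%), additive read noise (5 RFU; 0.001 OD),
  and a per-replicate (between-day) gain factor (CV 5%). All randomness
  flows from one seed; noise-free runs are bit-reproducible.

The quasi-steady-state (QSS) algebra of this model is available in closed
form (`qss_state`) and doubles as an independent oracle: in the slow-growth
limit the integrator must match it to better than 1%.

## Calibration of the named parameter sets

Measured quantities are encoded as generator ground truths. For each
T7RNAP variant set, the T7-promoter gain is solved in closed form against
the QSS fold-induction curve so that the maximum ground-truth fold over the
default titration equals the measured value (7.58 best reporter; 12.9
intact; 50.1 R632S; 43 split; 12.3 split-R632S; 16.3 / 1.42 SynZIP
variants). The competition coefficient `phi` is solved by root-finding on
the noise-free kinetic 2D titration of the strong-RBS AND circuit so that
the ground-truth maximal CFP suppression equals 46%. The crosstalk level and
complementation constant were chosen once so the optimized (RBS-250)
circuit's ground-truth AND score exceeds 8-fold. The analysis pipeline never
sees these calibrations — it must recover the values from noisy synthetic
data.

## Ratiometric pipeline (ratiometrics)

Relative T7-promoter activity is the mean blank-corrected YFP/CFP ratio over
the exponential-growth window. The window is the maximal contiguous run
where the log-OD slope is ≥ 0.7× its peak and corrected OD ≥ 0.02, at least
5 samples long; the slope is a Savitzky–Golay first derivative (window 9,
order 2) because raw centered differences fragment the run under read noise.
Fold-induction divides each replicate's activities by its own uninduced well
(per-replicate gain factors cancel exactly; the fold at the reference is 1
by construction). The dose-response fit is relative
(multiplicative-error-weighted) least squares of
`1 + (F-1) c^n/(K^n+c^n)` with a log-grid initialization over K; a curve
whose empirical maximum sits at an interior dose is fitted on the rising
limb only and flagged. The headline statistic is the empirical maximum of
the replicate-mean fold (the fitted asymptote is undefined for nonmonotone
curves), with the between-day s.d. across replicates. The empirical-maximum
estimator carries a small (≲2%) positive bias from selecting the largest of
several noisy dose means; the recovery tests budget for it.

## AND-gate statistics (gatecheck)

Titration grids condense each well to the mean blank-corrected intensity of
the last 10 cycles. Background is the (0,0) no-HSL condition, subtracted
replicate-matched; negative corrected values are retained so suppression
statistics stay unbiased. The AND score divides the maximal corrected RFP
with both inducers by the maximal corrected RFP with at most one, flooring
the denominator at 1% of the grid maximum (infinity sentinel when no
single-input cell is positive). Crosstalk indices and channel suppression
are descriptive ratios as defined in the API docs; ties in maxima break
toward the lowest (c6, c12) condition.

## Membrane model and spatial analysis (circuitsim.membrane, patternscan)

A row of 1 mm quadrants (default 24, genotype boundary between quadrants 12
and 13) runs the well model locally while the HSLs diffuse along the row:
explicit discrete Laplacian, no-flux outer boundaries, CFL-checked step
(D·dt/dx² ≤ 0.5; violations are rejected). Source modes: `uniform` ambient
concentrations; `spotted` fixed-concentration virtual nodes one quadrant
beyond each end (500 µM 3OC6HSL left, 200 µM 3OC12HSL right); `senders`
arabinose-induced per-quadrant synthesis by LuxI/LasI genotypes. Membrane
diffusivity and HSL stability in agar are not measured quantities;
`D = 0.03 / 0.02 mm²/min` (3OC6HSL / 3OC12HSL) and decay `2×10⁻⁴ /min` were
chosen once so gradients span roughly ten quadrants at 3000 min, and the
sender synthesis rate (`2×10⁻⁶ µM·min⁻¹` per enzyme·OD unit) so the
effective HSL at the far quadrants is sub-micromolar. The Laplacian groups
(left+right)−2c so exact mirror symmetry survives floating point.

Spatial background is the matched uninduced membrane (no arabinose / no
HSLs) — a different convention from the (0,0) grid correction, per the
respective assay designs. Profiles carry the s.d. across replicate membranes
(zero for a single row). Domain calls: peak = leftmost argmax; domain =
maximal contiguous interval ≥ half peak height (a declared convention);
symmetry = 1 − mean |mirror-pair difference| / peak height. Effective HSL
concentrations invert isotonic-cleaned standard curves piecewise-linearly in
log-concentration, reporting the bracketing standards and open intervals
beyond them.

## Hierarchy framework (hierarchy)

The iterated AND-induction scheme is qualitative, so it runs in discrete
synchronous rounds on a 1D lattice: founder halves produce morphogens a and
b; a rule induces its domain wherever both inputs exceed its threshold; each
new signal is produced by the newest domain and spawns two boundary domains
(AND with each flanking signal), for (2n − 1) planned domains. Open choices,
decided here: founder labels are the overwritable background while induced
labels are permanent (earlier levels win); same-level contention resolves by
specificity (the pair whose least-derived input is more derived claims
first — its qualifying region is nested inside its sibling's), then by
induction strength (product of inputs), then list order; per-rule thresholds
decay 0.7× per level (deeper signals are weaker); fields settle over 4
diffusion sub-rounds (iterated 3-cell box blur, retention 0.8) per induction
round. Defaults (threshold 0.8, 16 rounds, 64 cells) realize the full
hierarchy for n ≤ 4; deeper hierarchies need larger lattices/rounds and are
flagged incomplete otherwise.

## What the generator does and does not emulate

It emulates: sigmoidal dose-responses with basal leak; AND-logic RFP
requiring both HSLs; the nonmonotone intact-T7RNAP response; resource
competition suppressing CFP/YFP under high RFP; logistic growth; observation
noise with between-day gain effects; opposed 1D gradients from spotting or
sender synthesis across a 24-quadrant row. It does not model intrinsic
(stochastic) gene expression, molecular mechanisms of SynZIP or R632S
(effective parameter sets only), 2D membranes, surface-culture-specific
physiology, or fluorophore quenching; with the subsaturated complementation
default, RBS strength rescales fragment levels almost linearly, so the
background-reduction benefit of weaker RBSs is muted compared to the real
circuit. Passing tests therefore validate the statistical pipeline and the
declared model, not these unmodeled features of real data.

## Problem sizes

Characterization runs use 6–8 dose titrations × 3 replicates of 100-cycle
plates; titration grids are 6×6 conditions × 3 replicates; membrane runs are
24 quadrants for 3000 min at a 1-min step. These sizes keep every analysis
deterministic-fast while leaving the estimators' noise floors well inside
the stated tolerances.
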