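# Methods

## The measurement model the generator emulates

A SERS trace of an antibiotic solution or urine sample on the
400–1800 cm⁻¹ grid (2 cm⁻¹ step) is simulated as

    I(w) = k · g(c) · R(w)  +  Σ_j a_j F_j(w)  +  M(w)  +  b0 + b1·(w − w0)
           + ε(w),      ε ~ N(0, σ²) i.i.d. per channel

where

* `R` is the analyte's reference spectrum: a max-normalized sum of
  Lorentzian bands (default fwhm 12 cm⁻¹, a typical solid-state Raman
  linewidth). Identification bands carry relative amplitude 1.0, other
  listed bands 0.5, and the 803/835 cm⁻¹ bands shared by enrofloxacin and
  oxytetracycline 0.3. Enrofloxacin's peak list uses 1390 cm⁻¹ with
  1387 cm⁻¹ recorded as an alias, since both positions appear in common
  peak tables.
* `k = response_coeff · sensitivity` is the substrate response (a.u. per
  ppm). `sensitivity` is a per-analyte relative SERS cross-section
  (enrofloxacin 1.0, oxytetracycline 0.13, neomycin 0.0025); the matrix
  model carries the per-campaign response.
* `g(c) = c / (1 + c/c_sat)` is a Langmuir-saturating concentration
  response, linear below the substrate saturation scale `c_sat`
  (2000 ppm), so a 10,000 ppm sample sits well into the saturating regime.
* `F_j` are broad fluorescence bands (fwhm ≥ 200 cm⁻¹) with per-sample
  log-normal amplitude jitter; `M` collects sharp matrix bands (the
  urea-region band near 1000 cm⁻¹ in urine); `b0` jitters log-normally per
  sample while the slope `b1` is a fixed substrate property.

Per-row seeds are spawned from the design's master seed through
`numpy.random.SeedSequence`, so a dataset is bit-reproducible and any
single spectrum can be regenerated from the seed recorded in its manifest
row.

### Background dimensionality is a designed property

With three jittered fluorescence bands, a jittered offset, and one
constant direction (slope plus any unjittered matrix band), each scenario's
background spans exactly five sample-space dimensions, and analyte +
background matches the six-component model used for the pooled water and
spiked-urine fits. This is deliberate: when the factorization has surplus
capacity, the surplus components duplicate the dominant analyte direction
and split its loadings between near-collinear copies, which destroys
per-sample quantification. The in-vivo campaign re-jitters the urea band
(pig-to-pig variation) and is fitted after baseline subtraction with four
components (analyte, urea band, two fluorescence residuals).

### Calibrated constants

The platform's empirical sensitivities cannot be derived from first
principles, so the generator's noise and response constants are calibration
targets fixed once and then frozen:

* water: σ = 0.05 a.u., enrofloxacin response 1.0 a.u./ppm. The
  per-spectrum SNR at the identification bands then crosses the detection
  threshold (3) between 0.1 and 0.5 ppm, putting the univariate LOD at
  0.5 ppm; oxytetracycline and neomycin sensitivities place theirs at
  2.0 and 100 ppm.
* spiked urine: response 0.12 a.u./ppm, σ = 0.15, fluorescence amplitudes
  100–200 a.u. (jitter 0.25). Single-spectrum identification then fails
  below the 10,000 ppm level while the pooled six-component model detects
  every 10 ppm sample.
* in-vivo: day-1 effective level 30 ppm, day-7 three-fold higher with a
  doubled urea band.

Each was validated over 10–24 independent seeds before freezing.

## Preprocessing

Baseline correction is asymmetric least squares (λ = 1e5, p = 0.01,
10 reweighting iterations): the smooth curve hugs the lower envelope under
sharp bands, which suits fluorescence backgrounds. Two deliberate choices:

* Peak calling uses the *signed* residual. Clipping at zero first would
  put the median absolute deviation of the noise floor at zero and break
  the SNR denominator. Peak heights are measured above the signal-free
  median so height and noise share an origin (the asymmetric baseline
  leaves a small positive offset in the residual).
* The pooled six-component fits consume the raw spectra (clipped at zero,
  honoring the non-negative model) and let the factorization separate
  fluorescence and background itself. Baseline-subtracting first collapses
  the background to roughly one dimension and reintroduces the
  surplus-capacity splitting described above. The four-component in-vivo
  fit does run on baseline-subtracted data, because four components cannot
  span raw urine background plus analyte.

## The solver

Each ALS half-step solves its constrained subproblem exactly with an
active-set non-negative least-squares routine on the normal equations
(Lawson–Hanson as reformulated by Bro & de Jong), vectorized by grouping
right-hand-side columns that share a passive-set pattern (at most 2^k
patterns for k components, so the many-column half-steps cost a handful of
small factorizations). Singular passive-set systems fall back to a small
ridge term and are flagged on the result. Because every half-step is an
exact minimizer, the recorded lack-of-fit trace is non-increasing; the run
stops when the relative lof change falls below 1e-6 (default) or at
500 iterations, with a `converged` flag either way.

Initialization seeds the leading components with the reference spectra of
the analytes under study, re-estimated freely during ALS (a soft prior, not
a frozen constraint). The remaining components start from measured spectra
chosen greedily by residual norm after projecting out what is already
seeded, weighted by the fraction of the row outside that span — this
prefers background-dominated rows (blanks, high-fluorescence samples) and,
importantly, uses the row *as measured*: a projection residual would carry
artificial dips at the analyte channels, because projecting any
non-negative background onto a non-negative reference removes a positive
overlap. Unseeded fits use classic SIMPLISMA pure-variable selection
(purity σ/(μ + offset) with correlation down-weighting), with the pure
channels' intensity profiles regressed onto the data.

### Background smoothness regularization

Unconstrained ALS exploits a near-flat direction of the objective: a
background component can trade narrow dips or bumps at the analyte
channels against analyte contributions in the samples, because both sides
of the trade are non-negative. Measured against an oracle dictionary of
the true background shapes, this "rotational overfitting" inflated blank
contributions by an order of magnitude over the white-noise floor. Since
autofluorescence and substrate backgrounds are physically smooth, the
solver therefore replaces each non-seeded component that is essentially
broad — cosine ≥ 0.9 to its own Whittaker-smoothed version — with that
smooth version after ALS, then re-solves the contributions. Sharp
non-analyte bands (the urea component) fail the gate and are left intact.
Smoothing inside the ALS loop was rejected because it breaks lof
monotonicity; as a post-step, the ALS trace stays monotone and the returned
factors' lof is reported separately (`lof_final`, marginally above the last
ALS value by construction). The penalty (water 1e6, urine scenarios 1e5)
is matched to each campaign's background amplitude and curvature and ships
in the scenario defaults.

### Quantification for detection

Per-sample analyte intensity is read from the resolved components with two
robustness measures: contributions are summed over *every* component whose
spectrum matches the analyte reference (cosine ≥ 0.9), making the readout
invariant to occasional component splitting; and when the data matrix is
at hand the contributions are re-estimated by sign-unconstrained least
squares against the resolved spectra. The second point matters for the
blank-referenced detection rule: any residual systematic bias of the
background model then shifts blanks and spiked samples equally and cancels
in the cut, whereas non-negative quantification rectifies blank values at
zero and can produce a degenerate all-zero null. The fit's own C matrix
remains the non-negative solution.

## Detection rules

* Univariate: an analyte is identified in a spectrum when **all** its
  identification bands show a local maximum within ±8 cm⁻¹ of the
  reference position with SNR ≥ 3 (neomycin's single 977 cm⁻¹ band
  suffices). Noise is 1.4826·MAD over channels ≥ 24 cm⁻¹ from every
  reference band. The numeric rule stands in for by-eye identification,
  which software cannot reproduce.
* LOD: the lowest tested concentration whose replicate detection fraction
  reaches the rule (default: all replicates).
* MCR route: detection when the component intensity exceeds the blank
  mean + 3·SD; blanks are the unspiked samples of the same pool.
* Condition comparison: per-condition means with a separability check
  (consecutive means must differ by more than three combined standard
  errors, otherwise the ordering is reported "not separable").
* MRL screening: the intensity scale is calibrated from the level means at
  or below the MRL (least-squares slope through the origin); a sample is
  *positive* only above guard × I(MRL) (guard 1.5), *indeterminate* inside
  the guard band, otherwise *negative* with the detected flag carrying
  presence. The guard band absorbs calibration uncertainty exactly at the
  regulatory boundary, where samples spiked *at* the MRL would otherwise
  be coin-flips.

## Problem sizes

The packaged scenarios mirror the campaign sizes the analysis is designed
for: 59 aqueous spectra (6 blanks, ten levels × 5, three 1000 ppm
standards), 260 spiked-urine spectra (five levels × 50 + 10 controls), and
53 in-vivo spectra (13/20/20). The test suite and the acceptance script
regenerate these from scratch; the full suite runs in well under a minute
on one CPU.

## What passing tests do and do not show

The generator reproduces the statistical *structure* the analysis assumes
— additive smooth backgrounds spanning a low-dimensional space, i.i.d.
Gaussian channel noise, a monotone saturating concentration response, and
linearity of mixtures. Real urine adds effects outside the model: band
shifts and shape changes with matrix chemistry, spatially correlated
substrate noise, nonlinear fluorescence quenching, and day-to-day substrate
variation. Passing the calibrated LOD regressions therefore demonstrates
that the *analysis chain* recovers what the model says is recoverable at
the stated sizes and noise levels — not that a particular physical
substrate achieves those detection limits.

## Known limitations

* Rotational ambiguity is constrained (non-negativity, reference seeding,
  background smoothness) but not explored; a single solution is returned,
  with no feasible-band analysis.
* The blank null uses mean + 3 SD from few blanks (6–13 per scenario); its
  sampling noise occasionally (order a few percent of seeds) lifts the
  water MCR detection cut past the 0.1 ppm level.
* No closure, unimodality or hard equality constraints; no weighted or
  maximum-likelihood variants.
* Absolute concentration prediction (ppm from intensity) is out of scope;
  the screening calibration is used only to place the MRL cut.
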