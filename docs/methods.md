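# Methods

## Model of the cycling population

The simulator and the oracle share one model of an asynchronously cycling
progenitor pool. Each cell traverses G1 → S → G2 → M; cycle position is
measured in hours from birth (position 0), with half-open phase intervals
`[start, end)`. At the end of M the cell divides; both daughters inherit
the mother's analogue label status, and each daughter independently becomes
postmitotic (a PCNA⁻ neuron that never re-enters the cycle or acquires new
label) with probability `quit_probability`. There is no cell death, no
density regulation, and no distinct intermediate-progenitor sub-lineage:
proliferative vs differentiative division outcomes are represented entirely
by the quit probability.

Markers are derived states, not free parameters:

* **PCNA⁺** ⇔ the cell is cycling;
* **pHH3⁺** ⇔ the cell is in the terminal `phh3_g2_fraction` of G2 or
  anywhere in M (default 0.3 — pHH3 rises in late G2, but how "late" is not
  quantified in the literature, so it is configurable);
* **analogue⁺** (IdU/BrdU) ⇔ the cell, or any ancestor, resided in S phase
  while the analogue was available.

Label availability defaults to **persistent** (an injected analogue labels
any S-phase residence from injection to sacrifice), which is the assumption
under which the classic estimator arithmetic is exact; a **windowed** mode
(availability limited to a fixed number of hours after injection) is
provided for sensitivity analysis, as is a detection threshold (minimum
hours of labelled S-phase residence to score positive, default 0). At a
zero threshold, positivity is defined as being in S at any instant of the
*closed* availability window; this makes the instantaneous-labelling limit
(sacrifice coinciding with injection) reproduce the textbook labelling
index `t_s/t_c` exactly, and differs from "positive exposure time" only on
measure-zero boundary cases.

## The exact oracle

For deterministic phase durations and no cycle exit, every cell alive at
sacrifice time `T` descends from one founder with initial position
`a ∈ [0, t_c)`, and all of a founder's descendants share position
`(a+T) mod t_c`, labels and marker state. Expected class fractions are
therefore one-dimensional integrals over `a`, weighted by the founder's
descendant count `w(a) = 2^floor((a+T)/t_c)` and the initial age density
(uniform, or the exponential steady-state density ∝ `2^(1−a/t_c)`). Every
indicator involved is piecewise constant in `a` with closed-form
breakpoints, so the integrals are evaluated exactly on the elementary
partition — no quadrature error. Configurations outside this regime
(`phase_cv > 0`, `quit_probability > 0`) raise an unsupported-configuration
error; the quit-fraction estimator is instead validated against a high-n
run of the simulator itself (no closed form is claimed for it).

Because descendants of a founder share their class, a simulated snapshot is
a *weighted* sample of founders. Oracle–simulator comparisons therefore use
binomial standard errors at the design-effect-corrected effective sample
size `n_eff = n·E[w]²/E[w²]`, which the oracle computes in closed form.

## Simulator realisation

Per-cell phase durations are gamma-distributed with the nominal mean and a
common coefficient of variation `phase_cv` (0 = deterministic; the gamma
keeps durations positive with a realistic right skew). Initial positions
are drawn from the configured age density; the population then advances in
continuous time, vectorised generation-by-generation with numpy, so 10⁶
founders over a 24 h protocol simulate in ~20 s. Replicates ("embryos")
are simulated with independent sub-seeds spawned deterministically from a
master seed (`numpy.random.SeedSequence`), making every count table exactly
reproducible.

Postmitotic cells are assigned a normalized laminar depth by birth-order
quantile (earlier-born → deeper), a deliberately minimal stand-in for
radial migration used only to exercise the laminar module; it reproduces
the inside-out ordering of birthdating data but none of the migration
dynamics.

## Estimators, conventions and known biases

The estimator formulas are given in the README. Numerical and design
choices:

* **S-cell convention.** The S cohort defaults to *all BrdU⁺ cells at
  sacrifice* ("at-sacrifice"), which is what the stain admits; an
  "at-injection" option restricts it to cells in S at the BrdU injection
  instant (observable in simulation) for sensitivity analysis. Under the
  standard design (T_i = 1.5 h, sacrifice 0.5 h after BrdU) the
  at-sacrifice convention overstates T_S by the extra cells that enter S
  during that 0.5 h: the oracle puts the expectation at 4.5 h for a true
  4 h S phase (+12.5%), and T_C at 13.0 h for a true 11 h cycle (+18%,
  further inflated because a just-initialised uniform-age population
  doubles its youngest cohort within the protocol). The at-injection
  convention removes the T_S bias. The recovery harness always scores
  estimates against the *oracle expectation* and reports the bias relative
  to truth separately — biases are quantified, never absorbed.
* **T_G2 crossing.** Piecewise-linear interpolation, earliest crossing of
  50%; an exact 50% point returns that time. Three time points cannot
  constrain a parametric (sigmoid) curve, so none is fitted. Proportions
  that never bracket 50% raise a no-crossing error carrying the one-sided
  bound; non-monotone sequences are permitted but logged. With
  `phh3_g2_fraction = 0.3` the expected crossing for a true 1.5 h G2 is
  1.525 h (+1.7%).
* **T_M.** pHH3 covers late G2 plus M, so T_M = T_C · pHH3⁺/PCNA⁺
  systematically overstates M (expectation 1.12 h for a true 0.5 h M with
  the default marker window); this is a property of the assay, documented
  and reproduced, not corrected away.
* **T_G1.** Pure subtraction; a negative result raises an error carrying
  all four inputs rather than clamping, because inconsistency among the
  four estimates is diagnostic information.
* **Confidence intervals.** Replicate-level nonparametric bootstrap
  (resample embryos with replacement, B = 1000, percentile interval, fixed
  seed, index stream documented as
  `default_rng(seed).integers(0, n, (B, n))`) when ≥ 3 replicates; Wilson
  intervals for single-replicate proportions; degenerate intervals
  otherwise. In the joint model fit, T_S and T_C are resampled from the
  same dual-pulse replicates (they share embryos) while the other
  experiments resample independently; T_M and T_G1 draws are derived
  per-resample so the subtraction identity holds draw by draw. Percentile
  intervals are widened, if necessary, to contain the full-data point
  estimate.
* **Group comparisons.** Mann–Whitney U, two-sided, exact for tie-free
  groups of ≤ 8, asymptotic (tie-corrected) otherwise; all-tied data report
  p = 1 with a warning. Laminar bin distributions are compared by two-way
  ANOVA (group × bin, delegated to statsmodels) with per-bin t comparisons
  on the pooled residual mean square and Šidák adjustment over the ten
  bins.

## Laminar binning

Depth is normalised to [0, 1] with 0 at the pial surface; bin index is
`floor(10·d) + 1` with `d = 1.0` assigned to bin 10 (the deepest). These
boundary conventions are fixed by this package (the convention in the
field fixes only the bin count and that bin ten is deepest). Pairwise bin
merging conserves proportion mass exactly, and distributions are invariant
to cell order.

In the shift-detection validation, mass moved into one bin must come from
somewhere (ten proportions sum to 1), so "a shift in only bin 10" is
realised by spreading the compensation evenly across the other nine bins
and sizing it (+0.045 into bin 10, multinomial n = 800 per replicate, 4
replicates per group) so the per-bin compensation (−0.005) stays below
sampling noise while the bin-10 shift is ≈ 6 pooled standard errors.

## Problem sizes and what the tests show

Validation runs use 10⁴–10⁵ cells per replicate, 4 replicates, and 20
seeds per scenario (10⁶ founders for the quit-fraction self-oracle);
recovery tolerance is 15% relative to the oracle expectation. The
synthetic generator emulates steady-state kinetics, perfect markers and
exact counts; it does not model label bioavailability decay, marker
detection noise, apoptosis, inter-embryo kinetic heterogeneity, or tissue
geometry. Passing recovery therefore demonstrates that the estimators
correctly invert the labelling model they assume — not that that model
captures every property of real tissue. Estimates on real counts inherit
the assay biases quantified above.

## Known limitations

* The quit fraction after a persistent 24 h label counts all labelled
  progeny; its expectation has no closed form here and is defined by the
  high-n simulator itself.
* The oracle covers deterministic-phase, non-exiting populations only.
* The laminar depth model is ordinal, not geometric; only bin-level
  statements are meaningful.
* Counts are treated as exchangeable within replicates; spatial sampling
  (per-field vs per-ventricular-length normalisation) is out of scope
  because all estimators use ratios within a section.
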