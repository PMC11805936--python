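# Methods

`dioica` implements a dendroecological analysis of sex-specific growth,
water-use efficiency and climate sensitivity in a dioecious tree
population, together with a synthetic study generator that makes every
stage testable without field data.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Growth processing

**Basal area increment.** Ring widths (mm, Tucson/RWL format) are
converted core-by-core to annual basal-area increments
BAI_t = π(r_t² − r_{t−1}²) in cm² yr⁻¹, with r the cumulative radius from
the pith (an optional `pith_offset_mm` covers cores that missed the pith).
BAI is computed per core and then averaged per tree (`bai_combine:
core_mean`); the alternative — average the widths first, then compute BAI
(`width_mean`) — is implemented for sensitivity checks.  Computing per core
first preserves each core's geometry, which matters when cores of one tree
differ in length.

**Standardization.** Each tree's BAI series is divided by an OLS straight
line fitted against calendar year, yielding dimensionless ratio indices
with mean ≈ 1.  Ratio indices are the common convention for linear
detrending of mature-tree BAI; they fail when the fitted line crosses zero
inside the series, in which case the difference convention
(BAI − fit + 1) is applied and flagged (`detrend_fallback`).  The
regressor is calendar year rather than cambial age; within one tree the
two differ only by a shift, so the fitted trend is identical.

**Chronologies and pentads.** The per-sex chronology is the year-by-year
arithmetic mean of the standardized indices, with sample depth recorded.
For the pentad-level analyses, annual values are averaged over calendar
5-year blocks anchored at years divisible by 5 (1900–1904, 1905–1909, …),
so growth pentads align across trees and with the isotope sampling blocks;
pentads with fewer than `pentad_min_years = 3` contributing years are
dropped.  Historical stem diameter is back-cast from the measured diameter
by subtracting twice the tree-mean ring width of each year walking
backwards, truncating if the reconstruction would reach zero; the pentad
covariate `dbh_hist` is the mean reconstructed diameter over the pentad's
years.

## Carbon-isotope discrimination

Wood δ¹³C (‰ vs PDB, one pooled measurement per tree and pentad) is
converted to discrimination with the two-step model

Δ¹³C = (δ¹³C_air − δ¹³C_wood) / (1 + δ¹³C_wood/1000),

with per-mille values divided by 1000 inside the denominator — the only
dimensionally consistent reading of the formula.  The atmospheric
reference is an annual series averaged over each pentad's years, with
linear interpolation across interior gaps.  Δ¹³C is strictly increasing in
δ_air and decreasing in δ_wood on the plausible domain, and the
wood-solving inverse recovers Δ to 10⁻¹⁰ ‰ (tested).

## SPEI

The climatic water balance D = P − PET (mm month⁻¹) is accumulated over
backward k-month windows, k = 1…36.  For each (k, calendar month) cell the
accumulated values over the calibration years are fitted with the
three-parameter log-logistic CDF F(x) = [1 + (α/(x−γ))^β]⁻¹ using unbiased
probability-weighted moments (w₀, w₁, w₂ with weights C(n−i, s)/C(n−1, s)
on the ascending-sorted sample), and values are mapped through Φ⁻¹(F(x)).
This is the reference algorithm of the standard SPEI implementation.
Choices worth knowing:

- β ≤ 1 (infinite mean) or non-finite parameters mark the cell undefined;
  the cube records these in a fit-failure manifest rather than failing.
  The log-logistic PWM fit is intrinsically ill-posed for symmetric
  samples (its skewness is bounded away from zero), so near-Gaussian
  accumulations occasionally yield undefined cells — on the default
  synthetic climate this affects ≈ 1 % of the 432 cells.
- Probabilities are clamped to [10⁻⁶, 1−10⁻⁶] before the normal quantile,
  bounding |SPEI| at ≈ 4.75.
- The calibration period defaults to the full analysis window and is
  configurable; each calibration cell standardizes its own sample to
  |mean| ≤ 0.05 and |s.d.−1| ≤ 0.1 (tested per cell).
- A Thornthwaite (1948) monthly PET routine (heat index from the long-run
  monthly mean temperatures, day-length and month-length corrections,
  PET = 0 at or below 0 °C) backs tables that lack a PET column.

## Climate–growth correlations

The monthly correlation function computes Pearson r (two-tailed t test)
between a chronology and each of tmed/prec/cld/pet in 20 month slots from
April of the previous year to November of the growth year, on
pairwise-complete years, with per-cell significance flags at 0.05/0.01.
No multiple-testing correction is applied to mirror the per-cell
convention; a Šidák-corrected flag column is emitted alongside.

The lag surface correlates the chronology with SPEI at every combination
of 16 ending months (previous September … current December) and
accumulation scale 1–36 months.  "Lag k" means *k-month accumulation
ending at the stated month*, not a backshift of the 1-month index; the
surface peak is the argmax of r, ties broken toward the smaller lag and
then the earlier ending month.

A caveat established during validation: adjacent accumulation scales share
k−1 of k months, so surface cells are correlated at ≈ 0.98 and the
single-sample argmax scatters along a ridge around the true cell.  At
n = 60 years and signal-to-noise 1:1, an implanted 10-month legacy is
recovered within ±2 months of lag in ≈ 98 % of replicates, but a 30-month
legacy only in ≈ 60–70 % (an idealized iid-noise oracle puts the ceiling
near 72 %); across replicates the *modal* recovered peak is the true cell.
Single-study peak locations at long scales should therefore be read as
ridge estimates with ±(several months) uncertainty.

## Pentad-level linear models

Responses (pentad BAI, pentad Δ¹³C) are modelled with candidate terms
pentad (numeric start year), sex (sum-to-zero coded ±1), the tree's
previous-pentad response value ("ecological memory"), historical diameter,
and pentad×sex (only with both parents; the pentad covariate is
mean-centered inside the interaction so it is orthogonal to sex under
balance).  Memory and historical size parameterize the temporal
autocorrelation of repeated measures, which is why a tree random intercept
is screened rather than assumed: the same fixed structure is fitted by ML
with and without the intercept and compared on likelihood-based AICc
(k counts the extra variance); support requires the mixed model to be ≥ 2
units lower, and a boundary variance estimate (or a degenerate Hessian)
counts as "no support".

All marginality-respecting subsets are fitted by OLS on complete cases
fixed once (so AICc values are comparable), ranked by
AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k counting intercept,
slopes and error variance, and the winner is declared "superior" only if
it undercuts the runner-up by ≥ 2 units; ΔAICc against the intercept-only
null validates the winner.  Type-III term tests drop each column from the
full design.  Residual normality is gated with Shapiro–Wilk at
`shapiro_alpha = 0.05`; failing models with strictly positive responses
are refitted on the natural log and flagged.

**Stepwise climate regression.** Chronology-level regressions start from
the significant monthly correlation cells — runs of adjacent significant
months of one variable with equal sign are averaged into a single
predictor, following the convention of reporting merged month pairs — plus
the sex's surface-peak SPEI cell.  Forward steps enter the candidate with
the smallest coefficient p-value below `p_enter = 0.05`; entries that push
the design's maximum variance-inflation factor above `vif_max = 5` are
barred; each entry is followed by backward removal above
`p_remove = 0.10` (the just-entered term is exempt within its step, which
guarantees termination).  The full trace is always saved.  The thresholds
are conventional defaults — the procedure is named but not parameterized
in the literature this follows — and all are configurable.

## Synthetic study generator

The generator emulates a wet temperate-mountain site and a cohort like the
one analysed: monthly temperature with a seasonal cycle, +1 °C/century
trend and AR(1) (φ = 0.3) noise; gamma-distributed monthly precipitation
(CV = 0.45; right-skewed, as real monthly totals are — and necessary for
the log-logistic fit to be well posed) totalling ≈ 940 mm yr⁻¹; cloud
cover anticorrelated with temperature anomalies; Thornthwaite PET at
latitude 42.8°.  Sixteen male and fourteen female trees with ages drawn
uniformly in 37–140 / 54–142 years and 2–3 cores each.

Per tree, log BAI = log(base·(1 + 0.012·age)) + Σ β·z(climate terms) +
stand-level AR(1) (s.d. 0.28) + individual AR(1) (s.d. 0.35), with
per-sex sensitivities: males respond to 10-month SPEI ending January
(β = 0.18) plus smaller summer temperature/cloud terms; females to
30-month SPEI ending October plus previous-summer terms.  The log-linear
form keeps BAI positive and deliberately exercises the models' log branch.
Widths are recovered by inverting the BAI recursion
(w_t = 10(√(r² + BAI/π) − r)), measured per core with 0.05 mm noise and
quantized to the format's 0.01 mm.  These defaults put per-sex mean BAI
near 3.2/2.5 cm² yr⁻¹ and surface-peak correlations near 0.4–0.5, the
magnitude regime of real sex chronologies.

Isotopes are generated in discrimination space —
Δ¹³C(tree, pentad) = sex mean (17.51/18.15 ‰) + coupling·z(pentad BAI) +
noise (s.d. 0.11 ‰, half the repeatability bound of replicate wood
analyses), with coupling −0.40 ‰ per s.d. so growth and discrimination are
negatively related — then back-solved to δ¹³C_wood against a linearly
declining air series (−6.4 ‰ in 1900 to −8.0 ‰ in 2000).  Generating in
Δ-space makes the sign conventions literal: negative coupling ⇒ negative
BAI~Δ¹³C regression slope.

Every implanted coefficient is written to a truth ledger, and a fixed seed
produces byte-identical fixture files.

**What the generator does not emulate:** masting cycles and explicit
reproduction costs (sex differences enter only through growth rates and
climate couplings), ring-width measurement error structure beyond iid
noise, missing or false rings, pith-offset uncertainty, spatial
autocorrelation between trees beyond one shared stand-level disturbance,
and any trend in climate variance.  Passing the recovery tests therefore
shows the estimators work under the assumed data-generating structure, not
that real data satisfy that structure.

## Problem sizes and runtime choices

The test suite and the reproduction script run the full pipeline at the
study's own scale (30 trees, ~100 years, SPEI scales 1–36).  Replicate
simulations use 100–200 seeds for recovery-rate estimates, 1000 replicates
for the type-I-rate calibration of the correlation flags, and n = 10 000
for distribution-fit recovery — sizes at which the binomial/Monte-Carlo
error of each estimate is comfortably below the margin being asserted.

## Known limitations

- Cross-dating quality control is a leave-one-out inter-series correlation
  over the common period, not a segment-shifted procedure; misdated
  fixtures are detected only as depressed correlations.
- The stepwise procedure inherits the usual caveats of p-value selection
  (post-selection inference is not corrected); the trace and the VIF bar
  make its path auditable but not inferential.
- Pentads are calendar-anchored; studies that cut five-ring blocks per
  core from the bark inward would need a per-tree grid, which is not
  implemented.
- SPEI cells whose log-logistic fit degenerates are left undefined rather
  than falling back to another distribution family.
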