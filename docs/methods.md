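# Methods

## Model

Death counts on a Lexis grid of A 5-year age groups (20–24 … 75–79, so
A = 12 for the standard design) by P 5-year calendar periods follow a Poisson
log-linear rate model with person-years exposure:

    D_ij ~ Poisson(N_ij · λ_ij),   log λ_ij = μ + α_i + β_j + γ_k,

where k = A − i + j indexes the C = A + P − 1 synthetic birth cohorts
(k = 1 is the oldest: oldest age group in the earliest period). Effects are
sum-to-zero (effect-coded) within each block. The model assumes births and
deaths are uniform enough within 5-year bins that the central 5-year cohort
label is an adequate summary of the true ~10-year birth interval, and that
counts are conditionally Poisson (no overdispersion adjustment is offered).

## Identification and the Intrinsic Estimator

Because cohort = period − age holds exactly on the grid, the effect-coded
design matrix X (m = 2A + 2P − 3 columns) has rank m − 1; its kernel is
spanned by a single vector B0 whose entries within each block are linear in
category index. The package computes B0 numerically from the SVD (smallest
right singular vector; a hard error if the kernel dimension is not exactly 1)
with its sign fixed so the first age-block entry is positive.

The Intrinsic Estimator is realized by the principal-components route:

1. project the design onto the orthogonal complement of B0 using the
   non-null right singular vectors (an orthonormal basis U);
2. fit the reduced full-rank Poisson GLM with log person-years offset by
   IRLS (statsmodels GLM; deviance-change tolerance 1e−10, at most 100
   iterations, non-convergence raised with the deviance trace);
3. map coefficients b = U·b_r and covariance U·Cov_r·Uᵀ back;
4. reconstruct each block's omitted last category as the negative sum of
   the others, with its variance 1ᵀΣ_block1.

This is the minimum-norm solution in the effect-coded coordinate space and
is mathematically equivalent to the Moore–Penrose pseudo-inverse route, but
numerically stabler, and it makes the defining orthogonality (reduced
coefficient vector ⟂ B0) directly assertable.

A property worth knowing: minimum-norm is defined *in the reduced
coordinates*, so reversing the category order of every block relabels the
model but shifts the refitted solution by an exact multiple of B0 — the
effect levels are convention-dependent, as any resolution of the APC
identification problem must be. All estimable quantities (fitted counts,
second differences Δ²α, Δ²β, Δ²γ) are exactly reversal-stable, and the test
suite verifies them against an independently coded just-identified
constrained Poisson GLM (first two cohort levels equated). The reduced-space
convention is the one whose orthogonality the published coefficient tables
this package mirrors satisfy (their fully displayed columns have zero dot
product with B0 in reduced coordinates).

## Fit statistics

- deviance = 2·Σ[d·log(d/μ̂) − (d − μ̂)], with 0·log 0 ≡ 0;
- model rank = m − 1 = 2A + 2P − 4 effective parameters;
- AIC = (−2·logLik + 2·rank)/n per observation (full Poisson log-likelihood
  including the log d! term);
- BIC = deviance − (n − rank)·ln n.

These are the conventions of the APC software tradition this package
follows; the deviance-based BIC reproduces every published value it is
checked against to the 4-decimal precision of the printed inputs. The AIC
denominator (per observation) is inferred from the magnitude of published
values and cannot be confirmed more tightly without the original data.

## Rates, standardization, imputation

Age-specific rates are 100,000·deaths/person-years per cell. The ASMR is the
weighted mean of age-specific rates under a standard population restricted
to the included age groups and renormalized; the shipped default is Segi's
1960 world standard for ages 20–79 — weights (8000, 8000, 6000, 6000, 6000,
6000, 5000, 4000, 4000, 3000, 2000, 1000) — config-overridable.
Standardizing over 20–79 only (rather than re-weighting the full-life
standard) matches the case restriction of the study design; whole-life
standardization is out of scope.

Bins are 5 calendar years; a year missing from a bin is either a hard error
(default) or, under the `nearest-mean` policy, filled per age group by the
arithmetic mean of the k = 4 available calendar years nearest in time
(distance ties broken toward earlier years), applied to death counts and to
person-years separately before binning. "Nearest four years on counts" is
one reading of the gap-filling rule this follows; filling on rates instead
would differ when populations trend strongly across the gap.

Cohort labels use integer bin midpoints (start + 2): cohort midpoint =
period midpoint − age midpoint, so a 12×5 grid spanning 1989–2013 yields the
16 cohorts 1912–1916 … 1987–1991.

## WHO flat-file handling

The reader accepts the WHO Mortality Database comma-separated dialect
(Country, Admin1, SubDiv, Year, List, Cause, Sex, Frmat, IM_Frmat,
Deaths1..Deaths26; populations with Pop1..Pop26). Only age formats 00/01
(full 5-year detail) are accepted; coarser formats are rejected per row with
a warning and a reject count rather than disaggregated by guesswork. Ages
20–79 occupy columns 10–21 under both accepted formats. Sex codes map
1→male, 2→female; only female rows are retained by default. Rows with
non-empty subnational fields are excluded by default (national totals only)
to avoid double counting. Cause codes match by prefix (C50 covers C509), and
the built-in cause map is ICD-10 only (breast C50, cervical C53, ovarian
C56); earlier ICD revisions require a user-supplied cause map, since
historical code bridging is not something to invent. Missing-coded age cells
are treated as zero with a warning.

## Synthetic data generator

`make_effects` draws one smooth curve per block — a random cubic in
normalized index (coefficient scales 1, 1, 0.5, 0.25) plus Gaussian noise of
sd 0.05/smoothness — centers each block, and by default projects the stacked
coefficient vector off B0, so the truth is exactly the IE's estimand. With
projection disabled the generator exhibits the identification problem
itself: the IE then recovers the projected truth, not the raw truth, and a
test asserts exactly that.

Defaults emulate the 12×5 Korea-style design anchored at 1989. The baseline
rate is exp(μ) = 2×10⁻³ per person-year (200 per 100,000) with a flat 10⁶
person-years per cell. That baseline is the upper end of what any single
cancer site shows in reality; it is chosen so that every Lexis cell —
including the two corner cohorts observed in a single cell each, whose
coefficient uncertainty is ~1/√(cell count) — remains informative at the
exposures the recovery tests use. The generator reproduces the structure of
real mortality surfaces (smooth monotone-ish age curves, gentle cohort
waves, Poisson counts, WHO file dialect, missing calendar years) but not
their levels, age pyramids (exposure is flat by default), overdispersion, or
cause-coding noise — so passing recovery tests demonstrate correctness of
the estimator and plumbing, not field performance on any particular country.

Fixture files spread each cell across its 5 calendar years (deaths split
integer-evenly with the remainder to the earliest years; person-years split
evenly), so binning the written files reproduces the simulated table
exactly.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data:
grids up to 12×12, dual-route comparisons on 50–100 random grids with
A, P ∈ {3..6} at 10⁶ person-years per cell, and a 20-replicate simulation
study — sizes at which the full suite completes in seconds. Dual-route
agreement is asserted at 1e−6 on second differences and 1e−8 on deviance;
the kernel threshold is 1e−8 relative to the largest singular value; IRLS
tolerance is 1e−10 on the deviance change. Zero-death cells are valid
Poisson observations and are retained — including the very sparse
youngest-cohort cells that produce huge standard errors, which is faithful
to how such tables behave. Cells with zero person-years are invalid by
construction (a RateTable refuses them).

## Known limitations

- No overdispersion/negative-binomial variant and no alternative
  identification schemes (drift parameterizations, hierarchical APC).
- ASMR smoothing, joinpoint segmentation and EAPC summaries are out of
  scope.
- Real-data reproduction depends on the vintage of the WHO extract; the
  real-data test is opt-in (it runs only when an extract is present under
  `data/who/`) and tolerances of ±0.01 on coefficients should be read with
  that caveat.
- The AIC convention is documented-as-inferred (see above).
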