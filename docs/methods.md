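# Methods

## Model and assumptions

A SNP Z is a valid instrument for exposure X on outcome Y if (i) Z is
robustly associated with X, and (ii) Z affects Y only through X (no
horizontal pleiotropy, no confounding of Z with Y). Under those assumptions,
with per-allele summary effects β_ZX (SE_ZX) and β_ZY (SE_ZY) from two
non-overlapping GWAS cohorts, each SNP gives a Wald-ratio estimate of the
causal slope:

    β_XY = β_ZY / β_ZX.

Instruments are assumed pre-oriented to a shared effect allele
(harmonization does this) and approximately independent (LD clumping does
this). The outcome study here is a linear-model GWAS on binary case status,
so all effects — and all pooled estimates — are on the per-allele beta
scale; nothing is exponentiated into odds ratios.

### Per-ratio standard error

The default SE of a Wald ratio is the first-order delta approximation
SE_ZY/|β_ZX|, which neglects exposure-side noise; with exposure z-scores of
6–10, as in the bundled data, the neglected second-order term is below 2%.
A second mode, `paper_eq2`, implements the plain SE quotient SE_ZY/SE_ZX
found in some applied reports. That form is dimensionally inconsistent for
a ratio (it does not scale with the exposure effect), and produces ratio
SEs two orders of magnitude too wide on the bundled data; it is retained
for fidelity audits and is the convention under which the bundled
instrument set shows no heterogeneity (see Cochran's Q below).

## Estimators

**Simple median.** The pooled estimate is the equal-weight interpolated
median of the n Wald ratios: sorted values carry standardized cumulative
weights p_j = (S_j − w_j/2)/S_n and the median interpolates to cumulative
probability 0.5. It is consistent when at least half the instruments are
valid. Its SE is a parametric bootstrap: each replicate redraws
β*_ZX ~ N(β_ZX, SE_ZX²), β*_ZY ~ N(β_ZY, SE_ZY²) per instrument and
recomputes the median; the SE is the SD over replicates (default
n_boot = 1000, explicit seed, numpy PCG64 stream; draws are assigned to
instruments in rsID order so the SE is invariant to row order). CI is
estimate ± 1.959964·SE; the p-value is a two-sided normal test. The point
estimate never depends on the seed.

**IVW.** The inverse-variance-weighted estimate is the zero-intercept
weighted regression of β_ZY on β_ZX with weights 1/SE_ZY²:
Σ w β_ZX β_ZY / Σ w β_ZX². Fixed-effect SE is (Σ w β_ZX²)^(−1/2);
the default multiplicative random-effects mode inflates it by the residual
SD when that exceeds 1 (never deflates). Both modes share the point
estimate. On the bundled data only the random-effects p-value (0.625)
matches the source study's reported IVW p, which is why it is the default.

**MR-Egger.** The same regression with a free intercept, fitted by the
weighted normal equations after orienting all exposure betas positive (the
intercept is only interpretable on a consistently signed exposure axis).
The intercept estimates the mean directional pleiotropic effect; the slope
is the pleiotropy-adjusted causal estimate. SEs use the weighted normal
equations scaled by max(1, residual SD); p-values use t with n−2 df.
Requires ≥ 3 instruments and a non-degenerate design.

**Cochran's Q.** Q = Σ w_j (r_j − r̄)² with r_j the Wald ratios, w_j the
inverse squared per-ratio SEs, r̄ the corresponding weighted mean; p is the
upper χ²(n−1) tail. Under delta weights r̄ is exactly the fixed-effect IVW
estimate. Note the mode matters on the bundled data: delta weights give
Q = 16.45 (p = 0.021), while the `paper_eq2` convention — the per-ratio SE
form the source study states it used for its per-SNP confidence intervals —
gives Q = 0.34 (p ≈ 1.0), matching its "no heterogeneity" reading. Both
numbers are pinned in the test suite.

**Leave-one-out.** Re-runs the chosen pooled estimator on every
(n−1)-subset. Each row's bootstrap stream derives from (seed, removed
rsID) via a BLAKE2 digest, so rows are reproducible independently of
evaluation order. Published leave-one-out p-values depend on an unrecorded
bootstrap configuration and are reproduced only in their above/below-0.05
pattern; point estimates reproduce exactly.

## Instrument selection

Three-stage pipeline: (1) keep exposure SNPs with p strictly below 5×10⁻⁸
(p derived from β/SE by a two-sided normal test when absent); (2) greedy LD
clumping — rank by p ascending (ties by rsID for determinism), take the
best unremoved SNP as index, remove same-chromosome SNPs within 10,000 kb
whose r² with it exceeds 0.001, iterate; (3) drop SNPs with outcome
p ≤ 0.05. The clump window and r² conditions combine with AND — removing on
*either* condition would prune essentially every cis region down to one SNP
and contradicts the 8-instrument set the bundled analysis rests on.
Same-chromosome pairs missing from the r² reference are treated as
correlated by default (conservative removal; configurable). SNPs missing
from the outcome study are dropped and logged; proxy lookup is out of
scope.

## Harmonization

Shared SNPs are aligned to the exposure's effect allele: matching alleles
copy through; swapped alleles negate the outcome beta (audited by a
`flipped` flag); palindromic SNPs (A/T, C/G) with EAF in [0.42, 0.58] are
dropped under the strict default. When *neither* study reports an other
allele — the bundled fixture's situation, transcribed from a table with a
single effect-allele column for both studies — rows are treated as
pre-aligned and passed through with one logged warning. Harmonization never
touches SEs.

## Synthetic data

`simulate_two_sample` draws true exposure effects uniformly from a
configured range (positive by default), sets true outcome effects to
θ·β_ZX + α with α ~ N(pleiotropy_mean, pleiotropy_sd²), and adds
independent Gaussian noise at the two studies' SE scales (or SEs computed
from nominal sample sizes as (2n·maf(1−maf))^(−1/2)). Positions are laid
out in contiguous blocks with fixed within/between-block r². One seed is
split into four named streams (truth, exposure noise, outcome noise,
allele/MAF assignment) via `numpy.random.SeedSequence.spawn`.

Defaults mirror the bundled study's conditions: 8 SNPs, exposure betas
0.06–0.10 with SE 0.01, outcome SE 6.1×10⁻⁵, causal slope −0.001, no
pleiotropy, MAF 0.3–0.5, two LD blocks (r² 0.8 within, 0.0005 between).

What the generator does *not* emulate: individual-level genotypes, winner's
curse in instrument discovery, sample overlap between the two studies,
realistic allele-frequency spectra, or LD-induced correlation between the
summary *effects* (LD enters only the clumping reference). Passing tests
therefore demonstrate estimator correctness under the stated generative
model, not robustness to those real-data complications.

## Monte-Carlo checks and problem sizes

The calibration experiments in the acceptance suite use a well-powered
50-instrument design (θ = 0.1, exposure betas 0.05–0.15, SE_ZX = 0.005,
SE_ZY = 0.002 — per-ratio z ≈ 5): 500 replicates for simple-median CI
coverage (n_boot = 200 per replicate) and for the null (θ = 0) IVW type-I
error; the pleiotropy-detection experiment uses 200 replicates of 20
instruments with α ~ N(0.002, 0.001²) and SE_ZX = 0.002, chosen so
exposure-noise regression dilution (~θ·E[β_ZX]·SE_ZX²/Var(β_ZX)) is an
order of magnitude below the Monte-Carlo resolution. The whole suite runs
in well under a minute.

Known limitation: the parametric bootstrap SE of the median is mildly
conservative, because replicate centers are the *observed* ratios, whose
scatter around the common true slope adds to the within-replicate noise;
observed coverage is ≈ 97–98% at nominal 95%, and higher still in
very-low-signal regimes (per-ratio z ≲ 3).

## Numerical conventions

- 95% CIs use the normal quantile 1.959964 throughout.
- Reported rounding is three decimals, half away from zero (−0.0008 →
  −0.001), with −0.0 normalized to 0.0.
- P-values are floored at the smallest positive double to respect the
  (0, 1] domain under extreme z-scores.
- Ties in clumping rank break lexically on rsID; the clump result is
  returned in genomic-position order.
- Degenerate inputs fail loudly: zero exposure beta (undefined ratio),
  < 3 instruments for Egger, all-equal exposure betas (singular design),
  empty instrument sets, non-positive SEs.

## Design notes

- The bundled fixture stores the source table verbatim, including one SNP
  whose printed chromosome label is inconsistent with its position/gene
  annotation; clumping tests use synthetic data rather than relying on
  that row.
- The source study labels its pooled results "SE (estimate; CI; P)"; the
  leading number is treated as the point estimate, consistent with its CI
  and with direct recomputation.
- Bootstrap-dependent quantities (the pooled median's p-value, CI
  half-widths, leave-one-out p-values) depend on an unrecorded bootstrap
  configuration upstream; `reproduce_paper` flags them "approximate" and
  holds only point estimates to exact three-decimal reproduction.
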