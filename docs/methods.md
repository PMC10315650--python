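# Methods

## Setting and model

`mrchain` analyses a three-trait system — exposure X, mediator Y, outcome Z —
from GWAS summary statistics alone (two-sample MR). Each genetic variant j
used as an instrument for a trait contributes a Wald ratio
r_j = β_out,j / β_exp,j with first-order delta SE se_out,j / |β_exp,j|; the
estimators pool these ratios under different assumptions about instrument
validity. All effects are treated as generic linear coefficients; for
case-control GWAS they are log odds ratios, and results are also reported as
OR = exp(β) with 95% CIs exp(β ± z₀.₉₇₅·se).

The identifying assumptions are the usual instrumental-variable triple:
relevance (association with the exposure), exchangeability (no confounder
association) and exclusion (no direct outcome path). The instrument pipeline
enforces relevance by the genome-wide threshold p < 5×10⁻⁸ and LD clumping
(r² < 0.001, 10,000 kb window, greedy by ascending p with ties broken by
|β| then variant id, making the output row-order invariant); approximates
exchangeability by removing instruments genome-wide significant in a
confounder GWAS; and approximates exclusion by discarding instruments with
outcome p < 5×10⁻⁵. F = R²(N−2)/(1−R²) with R² = 2·EAF·(1−EAF)·β² is
reported per instrument; F ≤ 10 is flagged as weak but never auto-dropped —
F is a diagnostic, not a filter.

Palindromic (A/T, C/G) variants are dropped during harmonization by default,
before the outcome-association filter; the drop ledger records counts at
every stage so either ordering is auditable. An optional frequency-inference
mode (off by default) keeps palindromes whose EAF falls outside
[0.42, 0.58] in both studies and resolves strand from the minor-allele side.
Variant matching is by rsID only; positional matching is deliberately not
attempted (build ambiguity). Indels and multi-allelic records are rejected
at read time.

## Estimators

- **IVW.** Closed form β̂ = Σwr/Σw, w = 1/ratio_se². The primary mode is
  multiplicative random effects: SE = √(1/Σw) · √max(1, Q/(J−1)), which
  absorbs heterogeneity without ever deflating below the fixed-effect SE.
  P-values use a normal reference (a t reference is available via the
  `dist` argument).
- **MR-Egger.** Weighted regression of β_out on β_exp with free intercept,
  weights 1/se_out², after orienting all exposure betas positive (flipping
  the outcome beta together) so the intercept is interpretable as the mean
  directional pleiotropic effect. The residual dispersion is floored at 1
  (the same multiplicative-random-effects convention) and p-values use
  t(J−2). The slope is consistent under InSIDE even when every instrument
  is pleiotropic.
- **Weighted median.** Ratios sorted ascending; standardized cumulative
  weights s_j = (Σ_{k≤j}w_k − w_j/2)/Σw; the estimate interpolates the
  weighted CDF at 0.5. Consistent while valid instruments carry ≥ 50% of
  total weight. SE by parametric bootstrap (default 1000 draws of
  N(r_j, ratio_se_j²), seeded).
- **Maximum likelihood.** β_exp,j ~ N(γ_j, se_exp,j²),
  β_out,j ~ N(β·γ_j, se_out,j²). The γ_j are profiled out analytically,
  leaving the one-dimensional objective ½Σ(β_out−β·β_exp)²/(se_out²+β²se_exp²)
  minimized by Brent's method from the IVW start; the SE comes from the
  observed information with the γ block removed by Schur complement. As
  se_exp → 0 the estimator collapses onto fixed-effect IVW (unit-tested to
  1e-6), and with one variant it equals the Wald ratio.

First-order rather than second-order Wald-ratio SEs are used throughout:
the exposure associations are pre-filtered to be strong, making the
second-order correction negligible, and first-order is the common default.

## Sensitivity battery

**Cochran's Q** of the ratios about the IVW estimate, χ²(J−1) under
homogeneity.

**MR-PRESSO.** The observed statistic is the weighted residual sum of squares
of each variant against its leave-one-out IVW prediction. The null
distribution comes from parametric replicates that redraw both the exposure
betas (around their observed values) and the outcome betas (around the
leave-one-out predictions), re-deriving all leave-one-out slopes per
replicate. Redrawing both is essential for calibration: observed residuals
carry a β²·se_exp² variance component, and a null that holds the exposure
betas fixed lacks it, visibly skewing the global p below uniform. The
per-variant outlier test compares each observed squared residual to its own
simulated null with a Bonferroni flag at α/J; note the simulation p-value
cannot go below 1/(n_sim+1), so n_sim must exceed J/α − 1 for flags to be
possible (the default n_sim = 1000 comfortably covers α = 0.05 at J ≤ 49).
When outliers are flagged, the corrected estimate is IVW on the retained set
and the distortion test compares the induced shift against 1000 random
same-size removals.

**Leave-one-out** recomputes IVW omitting each variant, flagging omissions
that flip significance at the Bonferroni threshold 0.008.

**Steiger.** Variance explained summed per trait with the observed-scale
formula 2·EAF·(1−EAF)·β² (no liability-scale conversion — it is the one
variance-explained formula the pipeline defines); the direction is supported
when the instruments explain more variance in the exposure, with a two-sided
Fisher-z comparison of the implied correlations at the two sample sizes.
Exact ties resolve to "not supported".

## Mediation

indirect = β_XY·β_YZ, total = β_XZ + β_XY·β_YZ (the X→Z MR estimate enters
as β_XZ, following the two-step convention), with the first-order (Sobel)
delta variance β_XY²se_YZ² + β_YZ²se_XY². Zero covariance between the step
estimates is assumed — the three legs come from three non-overlapping
cohorts. The second-order product term se_XY²se_YZ² is available via
`second_order=True`. The proportion mediated is reported only when indirect
and total effects share a sign; a ratio of opposing effects is suppressed
with a warning.

## LD score regression

χ²_j = z_j² regressed on N·ℓ_j/M with a free intercept gives h²; the
z-score product z1·z2 regressed on √(N1N2)·ℓ_j/M gives the genetic
covariance ρ_g, and r_g = ρ_g/√(h²₁h²₂). Weights are single-step
heteroskedasticity weights 1/(1+N·h²₀·ℓ/M)² from an unweighted first pass
(1/((1+N₁h²₁ℓ/M)(1+N₂h²₂ℓ/M)) for the cross regression) — this captures the
dominant variance structure without full iterative reweighting. Intercepts
are always free, keeping estimates valid under modest sample overlap.
Uncertainty is a delete-a-block jackknife over contiguous blocks (default
200, automatically reduced to n_snps/2 for small panels); the r_g SE
propagates all three regressions through the same blocks. Non-positive
heritability estimates leave r_g undefined (reported as None with a
warning) rather than producing a complex number.

## Synthetic data

`simulate_chain_gwas` emulates three non-overlapping case-control GWAS
linked by the chain X → Y → Z with an optional direct X → Z path. Each trait
carries its own block of `n_snps` dedicated instruments (3·n_snps variants
total) — as in a bidirectional design where every trait has genome-wide hits
of its own — and effects propagate only downstream: X's instruments reach Y
via β_XY and Z via β_XZ + β_XY·β_YZ, Y's instruments reach Z via β_YZ, Z's
instruments affect Z alone. Per-instrument effects are drawn from
N(0.05, 0.02) truncated at |γ| > 0.01 so every instrument is detectable at
the default sample sizes. Observed effects add Gaussian noise with
SE = 1/√(2·EAF·(1−EAF)·N) — the coefficient SE for a standardized trait —
and p = 2Φ(−|β/se|) exactly, per record. Defaults encode the emulated study:
cohort sizes 385,276 / 807,553 / 257,811, step effects ln 1.309 and
ln 1.004, no direct path, EAF ~ U(0.05, 0.95), 10% palindromic variants, no
pleiotropy, outliers or LD unless requested.

Horizontal pleiotropy is modelled as direct X-instrument → Z effects
~N(mean, sd) on a configurable fraction of the X block; gross outliers
multiply chosen observed Z betas by a configurable factor (p-values
re-derived so records stay internally consistent). LD is equicorrelated
within consecutive blocks and zero across blocks, exposed as an explicit r²
matrix — the minimal structure needed to exercise clumping; the pipeline
takes LD as an input matrix rather than computing it from a genotype panel,
keeping the artifact download-free (variants absent from the matrix are
treated as independent and logged). `simulate_ldsc_panel` draws LD scores as
1 + Gamma(2, 20) and z-score pairs from the bivariate normal with the
standard LDSC second moments and unit null intercepts.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: realistic genome-wide LD and MAF spectra,
liability-scale effects for binary traits, sample overlap between cohorts,
population stratification (LDSC intercepts are exactly 1 by construction),
winner's-curse selection in the source GWAS, and effect-size–frequency
coupling. Recovery results on synthetic chains demonstrate the correctness
of the estimators under their own model, not robustness to these real-data
features.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale settings chosen to make
Monte-Carlo error small relative to the quantities checked: 200 replicates
for recovery and coverage (50 instruments, N = 100k), 1000 replicates for
null calibration (30 instruments), 50 replicates for robustness and outlier
detection, 200 for Steiger and the MR-PRESSO uniformity check, and a single
20,000-SNP panel for LDSC recovery. Determinism is end-to-end: every random
draw flows from an explicit seed, identical configurations give
byte-identical simulated tables, and `run_full` reports serialize to
byte-identical JSON across runs.

Degenerate inputs are handled explicitly: empty harmonization intersections
return empty results (logged) rather than raising; estimators raise a typed
insufficient-instruments error below their minima (2 for IVW, 3 for Egger
and the weighted median, 4 for MR-PRESSO); zero exposure betas are excluded
from ratio construction with a warning; constant LD scores raise a
degenerate-design error.

## Known limitations

- The confounder screen applies the exposure→confounder Wald-ratio reading
  of "delta method + random-effects meta-analysis"; pooling raw confounder
  betas would be an alternative reading.
- The direct effect in the mediation decomposition is the X→Z MR estimate,
  not a multivariable-MR direct effect; with substantial mediation the two
  differ.
- MR-Egger's intercept and slope are only identified under InSIDE; the
  package reports, but cannot verify, that assumption.
- The weighted median carries a finite-sample bias of order one ratio-SE
  toward the contaminated side under one-sided pleiotropy; it shrinks with
  instrument strength and sample size.
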