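# Methods

## Scope and assumptions

`mrmediate` implements two-sample Mendelian randomization (MR) with a
two-step mediation decomposition over three GWAS summary-statistics panels:
an exposure, a candidate mediator and a (typically binary) outcome, each
measured in a different sample. The standard instrumental-variable
assumptions are inherited: instruments associate with the exposure, are
independent of confounders, and affect the outcome only through the exposure
(relaxed by MR-Egger, which tolerates directional pleiotropy satisfying the
InSIDE condition, and by the weighted median, which tolerates up to half the
weight on invalid instruments). The mediation step additionally assumes the
three per-arm estimates are statistically independent, which is justified by
non-overlapping GWAS samples; the delta-method variances therefore carry no
covariance terms. This independence is an assumption of the design, not a
theorem: with overlapping samples the reported CIs would be anti-conservative.

All effects are carried on the log-odds scale (binary traits) or in SD units
(quantitative traits); odds ratios appear only in reports.

## Instrument selection

1. **Significance screen**: retain SNPs with exposure p < `p_threshold`
   (default 1e-5, the conventional relaxed threshold for traits with few
   genome-wide-significant loci; strict comparison).
2. **Greedy LD clumping**: visit SNPs by ascending p (ties broken by SNP id
   for determinism); each accepted index SNP removes remaining SNPs on the
   same chromosome within `clump_kb` kilobases (default 10,000) having
   r² ≥ `clump_r2` (default 0.001) with it. Output ordered by (p, id), hence
   invariant to input row order. LD arrives as a precomputed matrix file;
   SNPs absent from it are treated as unlinked and logged. A SNP whose only
   LD partners were themselves removed becomes its own index SNP — the
   standard greedy behavior.
3. **Strength filter**: F = (beta/se)² must exceed `f_threshold`
   (default 10). This is the summary-data approximation to the first-stage
   F statistic; no sample-size/R² variant is used because only summary data
   are available.

## Harmonization

Outcome effects are aligned to the exposure's effect allele: identical
alleles pass through, swapped labels negate the outcome beta and reflect its
EAF, strand complements are complemented first. Palindromic SNPs (A/T, C/G)
cannot be strand-resolved from labels; they are kept only when both EAFs are
present, both lie outside 0.5 ± `palindrome_eaf_window` (default 0.08, i.e.
drop when either frequency is in [0.42, 0.58]) and fall on the same side of
0.5 after label alignment — otherwise dropped. Instruments absent from the
outcome panel are dropped with a log entry; no proxy-SNP search is attempted.
Harmonization is idempotent, and the Wald ratio of a retained pair is
invariant to which allele either file called "effect".

## Estimators

With Wald ratios β̂ⱼ = ŷⱼ/x̂ⱼ and first-order SEs σⱼ = σ_yⱼ/|x̂ⱼ|
(exposure-side uncertainty deliberately ignored — the usual first-order
convention; consequently all estimators inherit weak-instrument attenuation
of order 1/F):

* **IVW**: β̂ = Σwⱼβ̂ⱼ/Σwⱼ, wⱼ = 1/σⱼ², equal by algebra to the
  zero-intercept WLS slope of ŷ on x̂ with weights 1/σ_y² (the test suite
  checks this equivalence against an independent WLS implementation at
  1e-10 relative). Cochran's Q = Σwⱼ(β̂ⱼ−β̂)² on J−1 df; when its p < 0.05
  the SE is inflated by √max(1, Q/(J−1)) ("multiplicative random effects",
  floored at the fixed-effect SE). Normal inference.
* **MR-Egger**: WLS of ŷ on x̂ with intercept, weights 1/σ_y², pairs
  oriented so x̂ⱼ > 0. Inference uses t(J−2) with multiplicative residual
  dispersion floored at 1, matching the IVW floor. The intercept estimates
  mean directional pleiotropy *on the exposure-increasing orientation*;
  with exact-fit data (zero residuals) the dispersion floor keeps SEs
  positive.
* **Weighted median**: sort ratios, normalize the IVW weights, compute
  cumulative midpoint ranks pⱼ = (Sⱼ − wⱼ/2)/S_J and linearly interpolate
  the ratio at p = 0.5. With equal weights and odd J this is exactly the
  sample median. The SE is a parametric bootstrap (default 1000 replicates):
  each (x̂ⱼ, ŷⱼ) is resampled from its normal sampling distribution, the
  weights recomputed, and the SD of the replicate estimates taken;
  deterministic given the seed, which the run manifest records.

`run_mr` applies every estimator the instrument count allows (J ≥ 3: all;
J = 2: IVW only; J = 1: single-SNP Wald ratio) and reports direction
consistency — all point estimates sharing one sign — as a tri-state flag
(None when fewer than two estimators ran; treated as not passing by the
screen, so 1-2-SNP analyses never pass the full filter).

## Screening and the pipeline

A screened trait **passes** iff IVW p < 0.05 ∧ direction-consistent ∧
Q p ≥ 0.05 ∧ Egger-intercept p ≥ 0.05. No multiple-testing correction is
applied anywhere — the screens are deliberately suggestive, and the manifest
records the number of tests so users can correct as they see fit.

**Reverse-causation screen.** Reverse MR is forward MR with the roles
swapped; `reverse_passed` is reverse-IVW p ≥ 0.05. By default the forward
analysis' instrument SNPs are excluded from the reverse instrument search:
under a genuine forward effect and a well-powered outcome GWAS, the
exposure's instruments reach the reverse significance screen and carry the
constant ratio 1/Z, which would flag "reverse causation" in essentially
every dataset. Excluding them asks the intended question — do
*outcome-specific* variants predict the exposure? (Directionality filters
based on explained variance are out of scope.)

**Mediator screen.** Step 1 (exposure→mediator) reuses one fixed instrument
set selected from the top exposure; step 2 (mediator→outcome) selects
instruments per mediator from its own panel. Both steps must pass the
three-part filter, and the survivor's indirect path must push the same way
as the total effect (sign(X·Y) = sign(Z)); failures are recorded with
reasons, never raised.

## Mediation decomposition

Indirect XY, direct Z′ = Z − XY, proportion XY/Z (undefined at Z = 0, which
raises). Delta-method variances as in the README; 95% CIs use the fixed
normal quantile 1.959964. The proportion's CI is reported on the raw
proportion scale (no logit transform) and may extend outside [0, 1] — an
honest reflection of first-order uncertainty for small mediated fractions.
Both the indirect effect's CI and the proportion's CI are reported, since
either may be the quantity of interest.

## Synthetic data

`simulate_chain` draws summary statistics directly (no individual-level
genotypes): per-SNP MAF ~ U(`maf_range`), per-study
se = 1/√(2·maf·(1−maf)·n) (standardized-trait approximation) and
beta_hat = beta_true + N(0, se), with three RNG streams derived from the
master seed — one per study — honoring the non-overlap assumption. P-values
are two-sided normal, so |beta/se| and p agree for every SNP by
construction.

The genetic architecture has four SNP classes: exposure instruments
(γⱼ ~ N(0, `gamma_sd`)), mediator-specific instruments (δⱼ ~ N(0,
`delta_sd`)), outcome-specific instruments (ηⱼ ~ N(0, `eta_sd`)) and null
SNPs. True marginal effects are exposure γ; mediator θ_XM·γ + δ; outcome
(θ_direct + θ_XM·θ_MY)·γ + θ_MY·δ + η + α, where α is the pleiotropic
effect applied to a `prop_invalid` fraction of exposure instruments
(balanced: mean 0; directional: mean `pleiotropy_mean`), injected on the
exposure-increasing orientation — the orientation whose average the Egger
intercept estimates. Mediator-specific instruments are what make the
second mediation step identifiable: with shared instruments only, every
step-2 ratio would equal Z/X and the estimated proportion would be
identically 1. Outcome-specific instruments are what give the reverse-MR
screen valid instruments to work with.

LD is block-diagonal: each causal SNP anchors a block of `ld_block_size`
SNPs padded with nulls (never two causal SNPs per block), adjacent SNPs
1 kb apart with r² decaying by `ld_decay_r2` per step; blocks are spaced
25 Mb apart across 22 chromosomes, beyond the clumping window. Marginal
effects of correlated SNPs are made LD-consistent via b ← R·b with
R the signed correlation matrix (r = +√r²).

**Default scenario** (`reference_scenario`): n_exp = 18,340,
n_med = 8,299, and n_out = 28,615 — the effective sample size
4/(1/cases + 1/controls) of a 7,300-case / 358,014-control binary outcome
GWAS, since binary-trait effects are simulated with the same normal model
and case imbalance enters only through n. True effects Z = ln 1.292,
X = ln 1.221, Y = ln 1.133 (true proportion mediated ≈ 9.73%);
23 exposure-instrument candidates with gamma_sd = 0.08 make roughly 11
instruments survive selection per replicate (range ~6-18), with F > 10
automatic because the p < 1e-5 screen is the stricter cut. Alleles are
drawn non-palindromic so harmonization never drops simulated instruments;
palindrome handling is exercised by dedicated fixtures instead.

What the generator does **not** emulate: realistic human LD maps and allele
frequency spectra, sample overlap, case/control liability-scale effects,
winner's curse in discovery, population stratification, or assortative
mating. Passing tests therefore demonstrate correctness of the estimators
and pipeline under the stated sampling model, not robustness to those
real-data complications.

## Numerical choices and problem sizes

* Fixed normal quantile 1.959964 everywhere; Egger uses t(J−2).
* Clumping ties at equal p resolved by SNP id; screen comparisons strict.
* Weighted-median interpolation uses `np.interp` over midpoint ranks;
  exact sample-median equality for equal weights/odd J holds to ~1e-12
  (floating cumulative sums).
* Bootstrap draws hitting x̂ = 0 exactly (measure zero) are nudged to the
  smallest positive float.
* Wald-consistency of input p-values is checked at 0.5 on the log10 scale;
  violations are logged, never dropped, since rounded published p-values
  can disagree with beta/se at fine precision.
* Simulation-based test sizes: 5,000 replicates for null calibration,
  1,000 for parameter recovery, 500 for Egger centering, robustness and CI
  coverage, 200 for end-to-end proportion recovery — sizes chosen so
  Monte-Carlo error is small relative to the tolerances being asserted.
  Calibration/recovery simulations for the Egger intercept and IVW mean
  use strong instruments (F well above 100) because with weaker instruments
  these estimators are attenuated by ~1/F (the NOME approximation) and are
  not exactly unbiased at any replicate count.

## Known limitations

* Per-SNP Wald SEs are first order; exposure-side noise mildly inflates Q
  under strong true effects and attenuates estimates by ~1/F.
* No MR-PRESSO, mode-based estimators, Steiger filtering, multivariable MR,
  proxy-SNP search or reference-panel LD computation.
* One mediator at a time; no joint multiple-mediator decomposition.
* Genome coordinates are treated as opaque beyond within-chromosome
  ordering; no liftover, no VCF input.
* Binary-outcome simulation uses an effective-n normal approximation rather
  than a liability or logistic sampling model.
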