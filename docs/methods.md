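# Methods

## Scope and data model

The package operates entirely on GWAS summary statistics.  One record is a
SNP's association with one trait: alleles, effect-allele frequency, the
per-allele effect (log-OR for binary traits), its standard error, p-value
and sample size.  Three tables enter the analysis — exposure, mediator(s),
outcome — drawn from non-overlapping cohorts (the two-sample assumption;
no sample-overlap correction is implemented).

## Instrument selection

Filters run in a fixed order, each appending a row to a telescoping ledger
(rows in = rows retained + rows removed, step by step):

1. **p-value threshold** — strict `p < 5e-8` for the exposure; mediators
   use a looser `p < 1e-5` because molecular traits rarely yield enough
   genome-wide hits to power an MR leg.
2. **LD clumping** — greedy by ascending p (ties broken by SNP id): a
   candidate is rejected if an already-accepted SNP on the same chromosome
   lies within 10,000 kb with r² ≥ 0.001.  Without an LD matrix this
   degrades to distance-only pruning, logged loudly; the result is then
   conservative (anything within the window blocks).
3. **Harmonization** — pairs matched by SNP id; palindromic (A/T, C/G)
   variants are removed unconditionally rather than frequency-rescued
   (an opt-in rescue keeping palindromes with |EAF − 0.5| > 0.08 could be
   added, but the default posture is removal; strand flips are resolved by
   complementing, and an outcome effect reported on the other allele has
   its sign flipped and EAF mirrored).  Allele sets that disagree even
   after complementing are ambiguous and dropped.
4. **Weak instruments** — per-SNP F = (γ̂/σ_x)², removing F < 10 (F exactly
   10 is kept, since removal is defined for F *below* 10).  The
   approximation (γ̂/σ_x)² is the default because the exact form
   (n−2)·R²/(1−R²) needs the per-study R²; it is available
   (`f_statistic_exact`) when EAF and n are present, with
   R² = 2·EAF·(1−EAF)·γ̂² on a standardized trait.
5. **MR-PRESSO outliers** (below) — skipped with a warning under 4 SNPs.
6. **Per-SNP Steiger filter** — drop SNPs explaining more variance in the
   outcome than in the exposure.
7. **Confounder blacklist** — a local annotation table standing in for a
   phenome-scanner lookup; removal is by case-insensitive substring match
   of configured confounder patterns.
8. **Outcome Bonferroni** — drop SNPs with outcome p < α/k (k = SNPs
   tested), i.e. variants directly associated with the outcome.

P-value thresholds are strict `<` everywhere; the F cutoff is inclusive
`≥`.

## Estimators

All estimators consume the harmonized (γ̂_j, Γ̂_j, σ_xj, σ_yj) and report
beta, SE, 95% CI (±1.96·SE) and a two-sided normal p.  Significance calls
(α = 0.05) are made by the pipeline, never inside estimators.

* **Wald ratio** β̂_j = Γ̂_j/γ̂_j, SE σ_yj/|γ̂_j| (first-order delta);
  the second-order variance σ_y²/γ̂² + Γ̂²σ_x²/γ̂⁴ is a switch.
  First-order ratio weights are the package default throughout.
* **IVW** — weighted mean of ratios with w_j = 1/SE_j².  Fixed-effects
  SE = (Σw)^(−1/2); the random-effects model is multiplicative,
  SE × max(1, √(Q/(k−1))), floored so it can never undercut the
  fixed-effects SE.  With a single SNP, IVW delegates to the Wald ratio.
* **Cochran's Q** = Σ w_j (β̂_j − β̂_IVW)², df = k−1, chi-square upper
  tail.
* **MR-Egger** — weighted least squares of Γ̂ on γ̂ with intercept,
  weights 1/σ_y², after orienting every γ̂_j ≥ 0 (flipping Γ̂_j in step);
  the orientation is required for the intercept to be identifiable.  SEs
  are scaled by max(1, √(RSS_w/(k−2))).  I²_GX = (Q_GX − (k−1))/Q_GX
  (floored at 0) quantifies NOME violation; below 0.9 a regression-dilution
  warning is logged.
* **Weighted median** — ratios sorted ascending; centred cumulative
  normalized weights s_j = (Σ_{i≤j} w_i − w_j/2)/Σw; linear interpolation
  at s = 0.5.  Consistent while valid instruments carry ≥ 50% of weight.
* **Mode** — Gaussian kernel density over ratios, modified-Silverman
  bandwidth h = φ·0.9·min(sd, MAD/0.6745)·k^(−1/5) (φ = 1), argmax on a
  512-point grid spanning the ratio range ± 3h; the weighted variant
  weights kernels by 1/SE_j².  All-identical ratios short-circuit to the
  common value with the IVW SE.  Grid size and φ are configurable.
* **RAPS** — pleiotropy as a zero-mean random effect with variance τ²:
  standardized residuals t_j = (Γ̂_j − βγ̂_j)/√(σ_yj² + β²σ_xj² + τ²)
  enter a Huber-ψ score (c = 1.345; Tukey biweight available).  β solves
  the robust profile score; τ² solves Σ[ψ(t_j)·t_j − δ_c] = 0 with
  δ_c = 2Φ(c) − 1 (the expectation of ψ_c(Z)·Z under standard normality,
  which makes the equation unbiased), floored at 0.  Both roots are found
  deterministically: the score is scanned on a 257-point grid over the
  ratio range (robust scores are non-monotone and vanish at ±∞, so simple
  bracket expansion is unreliable), each sign change refined by Brent's
  method, and among multiple roots the one minimizing the robust objective
  is kept.  The SE is the empirical sandwich estimate.  This deterministic
  profile formulation preserves the random-effect pleiotropy model while
  keeping results exactly reproducible without simulation.

Bootstrap SEs (weighted median, mode) are parametric — γ̂ and Γ̂ perturbed
by their SEs — with 1000 resamples by default, bit-reproducible under a
seed.

## Diagnostics

* **MR-PRESSO.**  For each SNP the expected outcome effect is its
  leave-one-out IVW prediction β̂_(−j)·γ̂_j.  The observed residual sum of
  squares is compared against `n_sim` parametric simulations drawing
  Γ*_j ~ N(β̂_(−j)γ̂_j, σ_yj) and γ*_j ~ N(γ̂_j, σ_xj); the global p is
  rank-based with an add-one pseudo-count, so it lives on a grid of
  1/(n_sim+1) and is super-uniform under the null.  Per-SNP outlier
  p-values compare each observed squared residual with its simulated
  distribution and are Bonferroni-scaled by k — so `n_sim` must exceed
  k/α for an outlier to be detectable at all (default 1000).  The
  distortion test bootstraps the outlier-free set and asks how unusual the
  before/after shift in the IVW slope is (two-sided rank p).
* **Steiger.**  Per-SNP variance explained r² = z²/(z² + n − 2); for a
  binary outcome the observed-scale correlation is taken as
  logOR·√(cf(1−cf))·√(2·EAF·(1−EAF)) (cf = case fraction) when EAF and the
  case fraction are available, falling back to the z-based form with a
  warning.  The overall test compares Σr²_exposure with Σr²_outcome via a
  Fisher-z two-sample test; because the exposure and outcome come from
  independent cohorts in a two-sample design, the independent-samples form
  is used rather than a dependent-correlations test.
* **Leave-one-out** IVW, flagging exclusions that flip the significance
  call; **funnel data** (ratio vs precision) for plotting; **power** for a
  binary outcome by the normal approximation
  power = Φ(|ln OR|·√(n·R²·cf·(1−cf)) − z_{1−α/2}), cross-checked against
  numerical integration in the tests.

## Decision rules

If the Egger intercept is significant at α, horizontal pleiotropy is
declared and Egger regression becomes the principal estimate.  Otherwise
IVW (random-effects, which equals fixed-effects when Q ≤ k−1) is
principal; a significant Q additionally emphasizes the weighted median.

## Mediation

All arithmetic is on the log-OR scale; ORs appear only at parse/format
boundaries ("OR(low~high)").  indirect = β₁β₂ with delta-method SE
√(β₁²SE₂² + β₂²SE₁²) (exact-variance term optional); direct = total −
indirect by construction, so total = direct + indirect holds to machine
precision.  The proportion indirect/total is invariant to rescaling the
mediator's units.  A bootstrap CI for the proportion is provided since no
closed form is standard.  The step-1 mediator screen uses unadjusted
α = 0.05 by default; BH-FDR is a config option.

**Formatting note.**  The mediating-ratio column is printed as a
two-decimal numeral with a percent sign, but the numeral equals the *raw*
fraction indirect/total (e.g. 0.006579/0.044017 = 0.149 printed "0.15%"),
matching the reference table this layout mirrors.  The raw fraction is
always carried alongside the formatted string; the discrepancy between the
numeral and the percent sign is surfaced here rather than silently
resolved.

## Enrichment

One-sided hypergeometric upper tail per gene set: drawing the query list
from the universe, P(overlap ≥ observed).  The universe defaults to the
union of all set members; supplying the assay's own background (e.g. all
measured proteins) is recommended.  Benjamini–Hochberg controls FDR.
Entity-level counts only — pathway-topology statistics ("reactions found")
require reaction graphs and are out of scope.

## Synthetic data

The generator emulates the three-cohort scale of a urate → plasma proteome
→ AF study: continuous exposure GWAS with n = 110,347; protein GWAS with
n = 3,301; binary outcome GWAS with n = 1,030,836 and case fraction
60,620/1,030,836.  Desk-scale defaults are 100 exposure SNPs and 30
cis SNPs per mediator — not the hundreds of thousands of SNPs and
thousands of proteins of the real assays; tests therefore exercise the
mechanics and calibration of the method, not its genome-wide bookkeeping.

Exposure architecture: a few large-effect loci (0.37, 0.22, 0.15, 0.12 SD
per allele, mirroring the handful of major urate transporters that
dominate its genetics) plus a polygenic tail N(0, 0.05²).  Mediator SNPs
carry cis effects N(0, 0.3²), typical of protein QTLs.  MAFs are uniform
on (0.05, 0.5).  Standard errors follow SE = 1/√(2·maf·(1−maf)·n), with
effective n = n·cf·(1−cf) for the binary outcome (log-OR approximation).

The causal identity total = direct + Σβ₁β₂ is enforced at construction
(the direct effect is derived).  Options: a palindromic-allele fraction,
an allele-flip fraction (outcome/mediator rows reported on the other
allele, undone by harmonization), balanced or directional horizontal
pleiotropy on a configurable fraction of instruments, LD blocks realized
as tag SNPs whose marginal effects attenuate by √r² (with the matching r²
matrix emitted), and point outlier implants.  The realized truth (per-SNP
effects, pleiotropy offsets, validity flags) is serialized as JSON next to
every dataset.

What the generator does **not** emulate: realistic LD maps, winner's-curse
selection in the source GWAS, sample overlap between cohorts, allele
frequency mismatch between cohorts, INDELs/multi-allelics, population
stratification.  Passing tests therefore show the estimators and filters
behave correctly under their stated models, not that any real-data result
is reproduced.

Monte-Carlo scale in tests: 100–200 seeds per stochastic property, 25–50
instruments per replicate — enough for the quoted tolerance bands (3 SE or
3 Monte-Carlo SEs) while the whole suite stays under a minute.

## Reference fixture

A 17-row table of published urate → protein → AF mediation results (ORs,
95% CIs, p-values, classifications, ratios) ships with the package as TSV.
Betas are recovered as ln(OR) and SEs as (ln hi − ln lo)/(2·1.959964); a
"<x" p-value is taken at its bound.  Eight of the seventeen printed ratios
are exactly recomputable from the printed three-decimal ORs; the rest
differ in the second decimal because the inputs are themselves rounded,
which is why the acceptance checks pin only those eight.

## Determinism

Every stochastic component (bootstraps, PRESSO simulations, the generator)
draws from `numpy.random.default_rng(seed)` with an explicit seed.  Output
files carry no timestamps or absolute paths; floats are written with
shortest round-trip repr.  Re-running a pipeline with the same config and
seed reproduces the output directory byte for byte.
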