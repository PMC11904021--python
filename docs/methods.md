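# Methods

## Model and assumptions

`mrmediate` estimates causal effects from two-sample summary-data Mendelian
randomization. For each instrument j the data are the per-allele association
estimates (β_X,j, se_X,j) with the exposure and (β_Y,j, se_Y,j) with the
outcome, taken from non-overlapping GWAS. The instrumental-variable
assumptions are the usual three: relevance (enforced empirically by the
p-value and F > 10 filters), independence from confounders, and exclusion
restriction (no effect on the outcome except through the exposure). The
diagnostics module exists because the third assumption is the one that fails
in practice (horizontal pleiotropy).

Binary outcomes are handled on the log-odds scale throughout: causal
estimates are log-odds ratios per SD of exposure, exponentiated for
reporting. Mediation combines three such MR fits by the product method:
mediated effect β3 = β1·β2, mediated proportion β3/β0, where β0 is the total
exposure→outcome effect, β1 the exposure→mediator effect and β2 the
mediator→outcome effect from the mediator's own instruments.

## Instrument selection and harmonization

Filters are applied in a fixed order — p-value, ambiguous-palindrome
exclusion, LD clumping, F filter — and every exclusion is logged with its
reason, so a selection is fully auditable. Defaults: p < 5×10⁻⁶ for the
forward direction (lenient, to give molecular traits a usable instrument
count), p < 5×10⁻⁸ for the reverse direction, clumping at r² > 0.001 within
10,000 kb, palindrome ambiguity at MAF ≥ 0.42, per-SNP F > 10 with
R² = 2·MAF·(1−MAF)·β² (MAF taken as min(EAF, 1−EAF); the formula is
symmetric in that choice). Clumping is greedy on ascending p-value with ties
broken lexicographically by SNP id, making the retained set independent of
input row order; cross-chromosome pairs are never clumped.

LD is consumed as data (dense matrix or sparse triplets with absent pairs
defaulting to r² = 0) rather than computed from a reference panel: the
algorithmic contract is an r² lookup, and supplying it keeps the pipeline
free of genotype handling.

Harmonization aligns outcome rows to the exposure's effect allele: identical
labels are copied, swapped labels negate the outcome beta and mirror the
EAF, strand complements are resolved by label for non-palindromic pairs, and
non-ambiguous palindromes are oriented by whether the effect allele is minor
on both sides — dropping only truly ambiguous cases. The F filter for a
binary "exposure" (reverse direction) applies the printed R² formula to
log-odds betas and emits a warning that the variance-explained scale is then
approximate.

## Estimators

* **IVW**: weighted least squares of β_Y on β_X through the origin with
  weights se_Y⁻², identical to the precision-weighted average of Wald
  ratios. Default standard errors use multiplicative random effects with the
  residual dispersion floored at one, se = se_fixed·max(1, √(Q/(n−1))) — the
  convention of the standard two-sample MR tooling; a fixed-effect model is
  available by flag. One instrument reduces exactly to the Wald ratio
  β_Y/β_X with first-order SE se_Y/|β_X| (the exposure-side uncertainty is
  ignored, adequate for F > 10 instruments).
* **MR-Egger**: the same regression with a free intercept after orienting
  every row to β_X ≥ 0 (required for identifiability; the flip negates both
  betas and leaves ratios unchanged). The intercept estimates the average
  directional pleiotropic effect; slope and intercept p-values use t(n−2),
  with the same dispersion floor.
* **Weighted median**: interpolated weighted median of the ratio estimates
  with normalized inverse-variance weights; consistent while valid
  instruments carry > 50% of weight. SE from a seeded parametric bootstrap
  (both betas redrawn from their SEs; default 1000 draws; SD of the
  bootstrap estimates).
* **Simple/weighted mode**: Gaussian-kernel density over the ratios,
  bandwidth φ·0.9·min(SD, MAD/0.6745)·n^{−1/5} (φ = 1 by default), argmax on
  a 512-point grid extended three bandwidths past the ratio range; uniform
  or inverse-variance weights; bootstrap SE as above. Identical ratios are
  returned exactly. The fixed grid makes the estimator exactly scale-equivariant.

P-values are two-sided normal for Wald/IVW/median/modes and t(n−2) for
Egger; all are floored at the smallest positive double so a reported p is
never zero.

## Diagnostics

Cochran's Q uses the fixed-effect IVW and first-order ratio weights
(w_j = β_X,j²/se_Y,j²), which is algebraically the weighted regression
residual sum of squares; p from χ²(n−1). The reporting IVW may be
random-effects, but Q and the MR-PRESSO residuals always use the classical
fixed-effect definitions — the two uses are deliberately distinct.

MR-PRESSO: observed RSS = Σ_j (β_Y,j − β̂_(−j)·β_X,j)² with β̂_(−j) the
leave-one-out fixed-effect IVW slope; the null distribution comes from
parametric replicates redrawing both betas (outcome around the
leave-one-out prediction). Global and per-SNP p-values use the add-one
estimator (1 + #{≥ observed})/(n_sim + 1), so they have resolution
1/(n_sim+1) and are never exactly zero; per-SNP p-values are
Bonferroni-adjusted by n_snp before the 0.05 outlier call. The replicate
count (default 1000, unstated in typical reports) and the seed are recorded
in every report. The distortion test compares the relative shift of the
outlier-corrected IVW against a null built by removing random subsets of the
same size — reported only when outliers exist. All PRESSO output is
bit-reproducible given (data, n_sim, seed).

Leave-one-out refits the IVW with each SNP removed, in input order; the
funnel table pairs each Wald ratio with its precision. Verdict thresholds
default to 0.05 everywhere and are arguments, not constants.

## Screening and tiering

A panel screen runs selection → harmonization → estimation → diagnostics per
exposure and assigns tiers from the IVW p-value alone (the primary method):
significant below 0.05/n_tests, suggestive in [0.05/n_tests, 0.05), null
otherwise, skipped when no instruments survive. n_tests is the full panel
size, not the count of non-skipped pairs, matching how panel thresholds are
conventionally quoted (0.05/91 ≈ 5.49×10⁻⁴, 0.05/1400 ≈ 3.57×10⁻⁵); whether
skipped pairs should shrink the family is genuinely open, and the fixed
convention is recorded in each ScreenRecord. Tiering is a pure function of
(p, thresholds), so re-tiering a manifest is idempotent. The bidirectional
report flags a trait unidirectional when the forward tier is
significant/suggestive and the reverse tier null — the precondition for the
mediation hand-off. Mediation candidates must have both legs significant at
the configured per-leg alpha; survivors are ranked by |mediated proportion|.

Mediated proportions are computed from IVW betas only; inconsistent signs
(sign(β3) ≠ sign(β0)) and |proportion| > 1 are flagged but reported
unmodified, because truncation would hide exactly the inconsistency the flag
marks. Delta-method uncertainty (se_β3 = √(β1²se2² + β2²se1²); the
proportion variance adds the β0 term, covariances taken as zero across
non-overlapping instrument sets) is optional, clearly-labelled output.

A note on the worked example shipped in the tests: with the reference
rounded inputs, 0.115·0.168/0.225 = 8.587%, while the reference table prints
8.55% for that row (its upstream computation evidently used unrounded
betas); the second row reproduces 5.78% exactly. The package always computes
from its own full-precision inputs.

## Synthetic data generator

`simulate_panel` emulates the structure of a cytokine-panel / metabolite /
disease-endpoint study: a continuous exposure GWAS (default n = 14,824), a
continuous mediator GWAS (n = 8,299), and a binary outcome meta-analysis
reported as logistic betas (n = 1,339,769). Defaults encode the headline
causal chain (β1 = 0.115, β2 = 0.168, total 0.225).

Per-variant instrument effects are drawn from Normal(0, 0.05²) truncated to
|effect| ≥ 0.02. The truncation bound is chosen so that, at the default
sample sizes and MAF range, a usable fraction of candidate instruments
clears p < 5×10⁻⁶ in every run while the effect-size scale stays in the
range typical of molecular-trait GWAS; it is a convention, and overridable.
Three disjoint variant sets carry effects: exposure instruments γ_j
(mediator inherits β1·γ_j, outcome inherits total·γ_j), mediator-specific
instruments δ_j (outcome inherits β2·δ_j), and disease-specific loci ω_j.
The separate mediator and disease loci mirror real panels — metabolite and
disease instruments are different loci from cytokine instruments — and are
what make the second mediation leg and the reverse direction estimable at
all. Horizontal pleiotropy adds direct outcome effects to a configurable
fraction of exposure instruments, mean-zero and independent of γ by default
(InSIDE satisfied), with switches for a directional mean and for
γ-correlated (InSIDE-violating) effects.

Observed betas add Normal(0, se) noise with se = 1/√(2·MAF·(1−MAF)·n) — the
standard-error approximation for a standardized trait — and p-values are
exact two-sided normal tail probabilities of β/se. LD is block-diagonal with
configurable block size and within-block r²; effect noise is drawn
independently across variants even within an LD block, so the generator's LD
exists to exercise clumping, not to model correlated summary statistics.
Allele-frequency columns are shared across the three traits (no
panel-to-panel frequency noise). These simplifications — plus the absence of
sample overlap, case-control ascertainment, population stratification and
winner's-curse-free effect reporting — mean passing tests demonstrate the
algorithms' correctness under the stated model, not robustness to every
artefact of real GWAS meta-analysis. One visible consequence: instrument
selection inside the simulation induces a mild winner's curse, so recovered
mediated proportions sit slightly below truth on average (still within the
delta-method CI at the tested sizes).

`inject_outliers` shifts named outcome betas by a fixed offset and
recomputes their p-values, keeping the dataset's Wald consistency invariant
intact; it is the fixture generator for the outlier-detection tests.

Determinism: one seed per config; per-trait noise streams are spawned from
it, so equal configs give byte-identical datasets.

## Numerical choices and edge cases

* Clumping ties broken by SNP id; empty candidate lists return empty sets
  rather than erroring; a selection yielding zero instruments produces an
  empty set with a warning, and the screening layer marks the pair skipped.
* R² values ≥ 1 (non-standardized betas) are capped just below 1 with a
  warning rather than propagating an impossible variance share.
* Duplicate SNP ids on read keep the smallest p-value; rows failing any
  field invariant are dropped and logged, never silently repaired (alleles
  are upper-cased, the one normalization applied).
* Summary I/O round-trips floats exactly (shortest-repr write, precise
  parse), including p-values at the 1e-300 scale.
* Mode estimator with zero ratio spread returns the common ratio; zero
  bandwidth inside a bootstrap replicate falls back to the weight-heaviest
  ratio.
* Calibration statements about the IVW test refer to the fixed-effect
  z-test, which is exact under the homogeneous null; the default
  floored-dispersion random-effects SE is deliberately conservative there
  (its rejection rate sits at or below nominal), as is the Egger intercept
  test under the same convention.

## Problem sizes used in validation

The test-suite and acceptance-script simulations use 30-SNP instrument
panels, 500 calibration replicates, 1000 MR-PRESSO replicates and bootstrap
draws, and sample sizes of 100,000 for recovery experiments — sizes at which
every targeted property (calibration within binomial error, recovery within
3 SE, unique outlier identification) is decidable in seconds while remaining
representative of the method's operating range.

## Known limitations

Single-mediator product-method mediation only (no multivariable MR
difference method, no correlated mediators); no proxy-SNP lookup for
instruments missing in the outcome; no Steiger direction filtering; LD is
trusted as supplied, not validated against a reference panel; first-order
Wald SEs throughout.
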