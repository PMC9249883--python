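# Methods

## Quantities and model

**Cq scale.** A quantification cycle (Cq) is the PCR cycle at which a
well's fluorescence crosses threshold; it is a log2-scale quantity
(one cycle ≈ one doubling) and higher Cq means lower expression.
Within a gene and tissue condition, replicate Cq values are modelled
as Normal(μ, σ²) with condition-specific μ and a gene-specific σ.

**Livak quantification.** For sample s, target T, reference R:
ΔCq(s) = Cq_T(s) − Cq_R(s); ΔΔCq(s) = ΔCq(s) − ΔCq(calibrator);
fold change = 2^(−ΔΔCq). Positive ΔΔCq = target down-regulated
relative to the calibrator. Two calibrator conventions are supported
because both appear in practice: the mean ΔCq over all normal samples
(`mean_of_normals`, the default) and each tumor sample's own adjacent
normal linked by patient (`paired_adjacent`). Results differ
per-sample but share the same expectation; the audit below accepts
either.

**Discordance audit.** Normalizing the same target against two
references A and B gives two ΔΔCq signs per tumor sample; a sample is
discordant when they differ. Exact zero is kept as its own sign
category (ties are measure-zero under the continuous model but must be
deterministic), and a missing well propagates to a missing sign, which
excludes the sample from the audit counts rather than raising.

**Overlap criterion.** A candidate reference R is eligible for target
T in a group when |μT − μR| ≥ 3·σT + 2·σR on a single consistent scale.
The 3/2 multipliers are fixed constants of the criterion (they come
from a tail-separation argument: ±3σ covers essentially all of the
target's distribution, ±2σ most of the reference's); the API exposes
`target_multiplier`/`reference_multiplier` overrides for sensitivity
analyses but defaults are never changed by the pipeline. Boundary
equality passes, directly per the "≥". Eligibility requires a pass in
*every* requested group; mixing Cq-scale and log2-expression-scale
statistics in one call is not supported — the caller picks one scale,
because the criterion is not invariant under changes of scale.

**Effect sizes and FWER.** The pooled screen fits, per gene, the
linear model expression ~ group on log2 values. ES is the fitted
group-difference coefficient (difference of group means) — an
unstandardized log2 quantity, not Cohen's d — and the p-value is the
ordinary pooled-variance two-sided t-test on that coefficient. No
empirical-Bayes variance moderation is applied; with hundreds of
samples per group the moderation gain is marginal and the unmoderated
test keeps the model fully transparent. The factorial contrast
(female.tumor − female.normal) − (male.tumor − male.normal) is tested
in the four-level cell-means model with contrast (1, −1, −1, 1); its
point estimate is algebraically identical to the difference of the two
sex-wise ES values, which is asserted in the tests. Family-wise error
is Bonferroni: fwer = min(1, p·G) with G = number of genes in the
tested matrix, per contrast (never pooled across contrasts). Samples
with unknown sex are excluded from intra-sex and interaction analyses
only. Genes with zero residual variance get p = 0 when ES ≠ 0 and 1
otherwise, with a logged warning — a degenerate case that only arises
in constructed data.

**Batch removal.** Additive per-batch offsets are estimated per gene
by a joint least-squares fit on group indicators plus sum-to-zero
batch contrasts, and only the batch component is subtracted. Because
ordinary least squares is linear, re-applying the operation yields
batch coefficients of exactly zero: the operation is idempotent, and
with batches balanced across groups the per-gene group-mean
differences are preserved exactly. A batch whose sample set coincides
with a group's is not estimable and raises an error naming the pair;
so does any other rank deficiency.

**Outlier flagging.** Hierarchical-clustering/PCA visual screening is
replaced by a deterministic rule: a sample is flagged when its mean
Pearson correlation to all other samples falls below
median − 3·MAD (raw median absolute deviation) of the per-sample
means; a fixed numeric cutoff can be supplied instead. Flagging never
removes samples — the caller decides.

**Raw counts.** RNA-seq count matrices are transformed to
log2 counts-per-million with pseudocount 0.5 and library-size
normalization before any statistic or model; everything downstream
then treats them as log2 expression.

## Synthetic data

`simulate_cq_experiment` draws each well independently from
Normal(μ_group, σ) per gene; pairs contribute one tumor and one
adjacent-normal sample with shared `pair_id`. The default spec
emulates a 17-pair papillary-carcinoma design with five genes whose
means/SDs sit in the lab-realistic regime: a high-variance reference
around 26 cycles (SD ≈ 4), a low-variance reference around 30 cycles
(SD ≈ 1.7) *inside* the target Cq range, and three targets at 26–29
cycles with SDs near 3 — i.e. precisely the regime where reference
choice flips calls. `simulate_expression_pool` builds
baseline + spiked subtype effect + additive batch offset + Gaussian
residual, with group sizes defaulting to a sexed 253-sample
multi-dataset thyroid compilation over three batches (offsets 0, +1.5,
−1.0 log2 units) and residual SD 0.5.

What the generators do **not** emulate: Cq heteroscedasticity at low
copy number, amplification-efficiency differences between genes
(Pfaffl-type corrections are out of scope), probe-level microarray
noise, non-additive batch effects, and censoring at the cycle limit.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to these real-data
features.

## The discordance-vs-margin law

The package's simulation property links the criterion to the audit:
for a non-differential target and two non-differential references,
mean discordance decreases monotonically as the criterion margin
(gap − required gap) grows, approaching zero at large margins.

A subtlety dictates how the margin must be swept. ΔΔCq subtracts a
calibrator ΔCq, so any per-gene constant — including the mean gap
μT − μR — cancels exactly; under the additive Gaussian model, moving
the reference *mean* alone provably leaves the sign distribution
unchanged. The part of the margin that does govern sign stability is
the SD term: the two references' ΔΔCq series share the target's noise
but carry independent reference noise, so their sign agreement is set
by the correlation σT²/(σT² + σR²)-ish, which rises as σR falls.
The sweep therefore holds the mean gap fixed (6 cycles, target
28 ± 1) and moves the margin through σR over seven points
(margin +2.9 → −3.0); 200 replicate 17-pair experiments per point give
mean discordance rising monotonically from ~2% to ~48% (Spearman ρ =
−1 against margin). This reproduces the mechanism the criterion
guards against — and explains why the criterion's mean-gap term
matters in *practice*: with a large gap, per-sample ΔCq never changes
sign, so single-sample statements ("target is above/below reference")
stay coherent even though the ΔΔCq calibrator would cancel a pure mean
shift.

## Numerical and interface choices

- Sample SD everywhere (n − 1 denominator). Groups with fewer than
  two present values report NaN SD/CV rather than erroring.
- CV% requires a positive mean; log2 matrices with non-positive means
  yield NaN CV for those records, and the scalar `cv_percent` raises.
- Display rounding (2 dp for stats tables, 1 dp for discordance
  percent) is cosmetic; all computation chains full precision, because
  CV% recomputed from rounded SD/mean cells does not generally
  reproduce the full-precision value.
- Missing Cq wells are explicit NaN, excluded pairwise; readers accept
  "", "NA", "N/A", "NaN", "Undetermined".
- Gene identifiers are case-preserving, matched case-insensitively;
  duplicate ids (after case-folding) are rejected at ingest.
- Scale detection on read: a matrix body written entirely as plain
  non-negative integer tokens is tagged `raw_counts`; any sign,
  decimal point or exponent forces `log2`. A `scale_hint` overrides.
- Tie-breaks are total and deterministic: candidate ranking orders by
  (suitability, |ES|, CV%, case-folded gene id); best-available
  selection breaks margin ties by gene id. Selection output is
  invariant to candidate input order.
- Seeds are explicit in every generator spec; no global random state.
  The acceptance script derives per-scenario seeds below 2³¹.
- Per-group statistics are computed on the matrix as supplied; batch
  removal is a separate prior step, so both orders
  (stats-before/after removal) are available by composition.
- `rank_candidates` treats fwer ≥ α (default α = 0.05) as
  non-significant, i.e. usable as a reference.

## Problem sizes

Defaults used by the test suite and examples: 17 pairs for Cq
experiments (the design the generator emulates), 100–300 genes for
pooled fixtures, 2,000 genes for the null FWER calibration, and
7 × 200 replicate experiments for the discordance sweep. These sizes
give Monte-Carlo error comfortably inside the asserted tolerances
(e.g. spiked-ES recovery is asserted within 3 standard errors of the
known truth) while keeping the whole suite fast on one CPU.

## Known limitations

- The criterion treats μ and σ as known; estimation error in small
  qPCR designs (n = 17) is not propagated into the pass/fail bound.
- Ordinary t-tests are anti-conservative for very small groups
  (e.g. a 2-sample subtype); the tool warns rather than suppresses.
- Additive batch model only; nonlinear or variance batch effects are
  out of scope.
- No amplification-efficiency correction: Cq arithmetic assumes
  doubling per cycle for all genes.
- The GEO/TCGA-scale meta-analysis numbers that motivated the method
  require the original accessions; this package validates the
  machinery on synthetic ground truth and in-table anchors instead.
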