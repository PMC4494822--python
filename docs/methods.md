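# Methods

`cnvscan` tests whether germline copy-number variation is associated with a
quantitative phenotype — percent mammographic density (PD) — directly at the
probe level of a SNP array, deferring all region formation to the
test-statistic track instead of to per-sample CNV calls. This note records
the model, the simulation that stands in for study data, the numerical
choices, and what the package's tests do and do not establish.

## The phenotype model

The response is √PD. PD is a percentage in [0, 100]; the square root both
stabilizes its variance and keeps the linear model's predictions inside the
representable range most of the time. Covariates are age (years), the
*reciprocal* of BMI ((kg/m²)⁻¹ — density falls with BMI, roughly
hyperbolically), and a menopausal indicator. The predictor of interest is,
depending on stage, a probe's Log R Ratio (LRR), a SNP dosage (0/1/2), or a
deletion-carrier indicator.

Two variants:

* **Ordinary linear model** — used for unrelated cohorts and throughout the
  permutation machinery.
* **Family random intercept** — one Gaussian intercept per family, fitted by
  maximum likelihood (statsmodels `MixedLM`); the minimal mixed model that
  accounts for a multigenerational family design. No kinship matrix: within-
  family correlation is treated as exchangeable. Non-convergent fits fall
  back to the ordinary model and are flagged `mixed_fallback`.

Inference on the predictor is a Wald t (coefficient over its standard
error); p-values use the t reference with residual degrees of freedom.
Degenerate probes (no predictor variance, or an exact fit) report t = 0 with
a `degenerate` flag rather than raising, so a genome scan never halts
mid-track.

Genome scans use a vectorized ordinary-least-squares engine: response and
every LRR column are residualized on the covariates (Frisch–Waugh–Lovell),
after which each probe's joint-model Wald t is a simple-regression slope t
with n − p − 1 degrees of freedom. The engine is tested against statsmodels
to 1e-8 and is what makes permutation inference tractable (one matrix
product per permutation batch instead of per-probe model fits).

## Quality control

LRR is median-centred per genotyping plate (subtract the plate's pooled
non-missing median — the simplest reading of per-plate median
normalization; idempotent by construction). Samples are then excluded when
any of four metrics *strictly* exceeds its threshold:

| metric | definition here | threshold |
|---|---|---|
| `lrr_sd` | SD of non-missing autosomal LRR | 0.35 |
| `baf_drift` | fraction of BAF strictly inside (0.2, 0.25) ∪ (0.75, 0.8) | 0.0015 |
| `wave_factor` | SD across 1,000-probe windows of the per-window median LRR | 0.05 |
| `n_cnv_intervals` | maximal runs of ≥ 3 consecutive probes with 3-probe running-mean \|LRR\| > 0.25 | 500 |

The thresholds are the standard array-QC values; the *formulas* are this
package's own deterministic desk-scale analogues of the named metrics (the
usual implementations are tied to a specific caller's internals). Missing
values are excluded from every metric, never imputed. The interval count is
computed after normalization.

## Segmentation

Circular binary segmentation on the per-chromosome |t| track. On each
interval the values are arranged on a circle and the cut pair (i, j)
maximizing the pooled-variance two-sample t between arc and complement is
located; the split is accepted if its within-interval permutation p ≤ α and
the procedure recurses on the pieces. Numerical points:

* For a permuted interval the total sum and sum of squares are invariant, so
  |t| is a monotone function of the *between-arc sum of squares*
  (t² = (m−2)·B/(SS_tot−B)). Both the argmax and all shuffle comparisons are
  computed on the B scale from prefix sums alone — the key performance
  lever.
* Defaults: α = 0.01, 1,000 within-interval shuffles, minimum arc width 2,
  early stopping once acceptance is impossible (the shuffle loop then
  returns its conservative running estimate). All shuffles are seeded.
* Ties in the argmax break to the first pair in lexicographic (i, j) order —
  the leftmost, shortest arc — with a 1e-9 relative tolerance because the
  two (i, j) representations of the same circular partition can differ by
  rounding.
* Wrapping arcs map back to two linear cut points; a cut at an interval edge
  contributes a single change-point.

Candidate segments must span ≥ 3 probes with mean |t| strictly greater
than 1. Under a null, |t| is half-normal with mean ≈ 0.8, so a long flat
chromosome can qualify wholesale; a configurable guard (on by default)
additionally requires the segment mean to exceed the chromosome-wide mean
|t|. Adjacent qualifying segments are never merged. Candidates are expanded
by 6× their probe count on each side, clipped at chromosome ends (a
10-probe segment → 130 probes unclipped).

## Permutation inference

Per permutation: PD is shuffled across QC-passing samples — covariates stay
with their sample, so the permutation breaks the phenotype–signal *and*
phenotype–covariate associations, matching a plain phenotype permutation;
family structure is ignored (full exchangeability). Probe models are
refitted only inside the expanded region, CBS runs on the permuted |t|
values, and the statistic is the mean |t| of the best segment with ≥ 3
probes — or the whole-region mean when no segment qualifies, which is
conservative (it can only raise the permuted statistic, never lower the
observed rank).

p = (n_exceed + 1)/(B + 1), ties counting as exceedances. This is the
convention under which the attainable floor is exactly 1/(B+1) — 1/10,001 at
the standard B = 10,000. Discovery significance is p < 1/10,000 (only the
floor qualifies); replication uses 0.05.

The observed statistic is the mean |t| over the originally identified
segment. For calibration experiments on windows that were *not* selected by
a scan, `observed_segment_stat="best"` applies the identical CBS-best-
segment rule to the observed track, which makes observed and permuted
statistics exchangeable and the null p-value exactly uniform (up to the
1/(B+1) grid).

The conditional variant adds the region's most significant SNP as a fixed
covariate in every model, observed and permuted alike. A constant SNP column
reduces exactly to the unconditional test.

## Forced copy-number calling

In a fixed window the segmentation problem disappears and calling is a
five-way decision per sample. Each state c ∈ {0..4} scores every probe's
LRR under N(μ_c, σ²) with μ = {−3.5, −0.45, 0, +0.4, +0.68} (conventional
array cluster displacements; configurable) and every SNP probe's BAF under
the state's cluster mixture: uniform for c = 0, otherwise Gaussians at k/c
with Binomial(c, ½) weights, cluster SD 0.04, plus a 2% uniform outlier
component. The call is the arg-max of the summed log-likelihood; the score
is the margin over the runner-up. Deletion carriers are calls < 2 (a
duplication contrast > 2 is also available), and carrier status replaces
LRR in the phenotype model.

Because the caller's default state means are shared with the simulator,
call-accuracy tests are generative-model recovery tests — they certify the
decision machinery, not robustness to miscalibrated cluster positions. The
mixture weights assume allele frequency ½ while the simulator draws
per-probe frequencies in (0.1, 0.9); the LRR term dominates, so this
mismatch is tolerated by design.

## The synthetic cohorts

The generator emulates a family-based density GWAS: 89 families of 4–9
women by default (≈ 580 samples, matching a few-hundred-women
multigenerational design), age ~ N(57.2, 11.6), BMI ~ N(27.1, 5.7)
truncated at 15, menopausal = (age > 51) XOR 10% noise — the covariate
distributions of such a cohort. √PD = 6.1 − 0.04·age + 40/BMI − 0.6·meno +
γ·(copies − 2) + family intercept (SD 0.6) + residual (SD 1.1), clamped to
[0, 10] before squaring (PD is a percentage); with γ = 0 this yields PD
with mean ≈ 26, SD ≈ 15. LRR = state mean + sinusoidal genomic wave
(amplitude 0.02, period 1,500 probes, random phase per sample) + per-plate
shift (SD 0.03, 96-well plates) + N(0, 0.15) noise. BAF clusters follow the
copy-number state with per-probe B-allele frequency ~ U(0.1, 0.9), cluster
noise 0.03; intensity-only (non-SNP, 10% of) probes have missing BAF.
Deletion/duplication carrier status is Bernoulli per sample; a third of
carriers are homozygous (copy 0, resp. 4) — the ratio seen in catalogued
common deletion regions. One master seed drives a named per-stage seed
sequence; identical configurations are bit-reproducible.

What the generator does *not* model: CNV transmission within families
(carrier status is independent per sample; only the phenotype carries the
family correlation), reader/scanner drift in the density measurement,
GC-content-linked waves (the wave is a pure sinusoid), linkage
disequilibrium structure beyond the single injected SNP, and raw X/Y allele
intensities. Passing tests therefore certify the statistical machinery under
a faithful but idealized signal model, not performance on real array data.

The linked-SNP generator ("copy then perturb") starts from the carrier
indicator and re-draws a fraction 1 − √r² of samples from the permuted
marginal, giving realized r² ≈ target (logged); the SNP is named after the
SNP probe nearest the region midpoint so positional SNP selection finds it.

## Problem sizes in the test suite

Experiments are sized for a single desk-class core: type-I calibration uses
200 samples × 2,000 probes with 200 ten-probe null regions at B = 500;
recovery and conditional experiments use 50 replicates of 200–240 samples
with B = 200 and 99 respectively; permutation-internal CBS uses 100
shuffles per split test. The acceptance script runs one genuine B = 10,000
region test to exhibit the 1/10,001 floor. These sizes are the package's
standing desk-scale study conditions; every constant of the method itself
(QC thresholds, the ≥ 3-probe / mean > 1 filter, the 6× expansion, the
significance rules) is used at its standard value throughout.

## Known limitations

* The mixed model is a random intercept, not a kinship model; permutations
  ignore family structure (a within-family permutation mode exists on
  `permute_region`'s machinery only insofar as the caller pre-stratifies —
  full exchangeability is the default and the tested path).
* Probe p-values are Wald, not likelihood-ratio.
* Genome-scale scans with the mixed model fit one `MixedLM` per probe and
  are impractical beyond a few thousand probes; the vectorized engine covers
  the ordinary model only.
* At desk scale an embedded region is a visible fraction of the whole
  "genome", so extreme carriers (copy 0) measurably inflate their own
  LRR-SD and BAF-drift QC metrics — an artefact of small probe counts, kept
  in mind when sizing test cohorts (regions are ≤ 1% of probes).
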