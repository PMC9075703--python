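# Methods

This note documents the models and procedures telogene implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Telomere-length estimation

A read is *telomeric* if it contains at least `k` non-overlapping exact
copies of TTAGGG, scanned left to right in the stored orientation
(`k = 12` by default, matched to ~151 bp reads: 12 copies occupy 72 bases,
so a read must be at least half repeat).  Reads shorter than 6k bases can
never qualify and count only toward the GC denominator; no length
re-weighting is applied.  Two behaviors the motif-counting literature leaves
open are exposed as flags: `both_strands` also scans CCCTAA and takes the
per-read maximum, and `overlapping` counts overlapping matches.  Defaults
are single-strand, non-overlapping.

The GC window [0.48, 0.52] is inclusive on both ends; N bases count as
non-GC.  The length constant `c` (genomic length at matching GC divided by
the number of chromosome ends) is a required input — there is no silent
genome default, because it depends on the reference and the GC window.  The
synthetic pipeline computes the matched constant analytically from its own
generating parameters (`ReadSimSpec.expected_counts`).

## Read simulation

`ReadSimSpec` abstracts the genome to a total size (`genome_size`, default
1e6 — a scaled-down genome that keeps the telomeric fraction large enough
to measure at 1e4–1e5 reads) and `n_chrom_ends` (default 46, human).  A
read is telomeric with probability
`true_tl * n_chrom_ends / genome_size * batch_shift`; `batch_shift` is a
multiplicative technical bias on telomeric-read recovery.  Telomeric reads
are perfect tandem arrays at a uniform phase with per-base substitutions at
rate `1 - telomere_purity`; background reads draw per-base GC from a
mixture, so a read's GC count is exactly Binomial(L, gc) within a
component, which makes the expected GC-window count available in closed
form.  With `telomere_purity = 1` the expected telomeric count, GC-window
count and implied TL estimate are all analytic; the estimator is tested
against those expectations.  Not emulated: sequencer error profiles,
quality scores, mapping artifacts, interstitial telomeric repeats.

## Batch correction

Filters keep autosomal bins with mappability exactly 1.0 and no blacklist
flag (CNV/SV exclusion is a user-supplied list; nothing is bundled).
Within-sample normalization divides each sample's row by its own mean depth
over retained bins; each bin column is then centered across samples.  This
makes components scale-free (total-depth differences cancel) and mean-zero,
which the downstream regression requires.

The randomized SVD uses a Gaussian sketch of `n_components + oversampling`
columns (default oversampling 10), two power iterations with QR
re-orthonormalization, then an exact SVD of the projected matrix;
deterministic for a fixed seed.  Scores are `U * S`, which are exactly
orthogonal and — because the range basis of a column-centered matrix stays
orthogonal to the ones vector — exactly mean-zero.  When the sketch width
reaches the smaller matrix dimension the decomposition is exact; the test
suite exploits this for oracle comparisons against `numpy.linalg.svd`.
The default of 200 components reflects the scale of a multi-study WGS
resource; the synthetic pipeline uses the planted rank, and the
`component_diagnostics` table (residual correlations with reference
measurements, one-way between-group R² for batch labels) is the instrument
for choosing the count on real data.

TL adjustment regresses TL on an intercept plus the leading scores and
returns residuals plus the intercept: bp units and the sample mean are
preserved exactly (mean-zero scores make the intercept the mean).

## The two-stage mixed model

Stage 1 fits `y = Xb + g + e` with `g ~ N(0, sg2 K)` and an independent
residual variance per study/population group.  `K` is the relatedness
matrix with unit diagonal (twice the kinship coefficient: 1 for self, 0.5
for full sibs/parent-offspring) — singleton samples therefore contribute an
identity block.  Variance components are estimated by average-information
REML: variances floored at 1e-10 x total phenotypic variance, convergence
when the relative restricted-likelihood change falls below 1e-6, at most
100 iterations, step-halving whenever a proposed update would decrease the
likelihood.  Non-convergence raises an error carrying the iteration trace.
The covariance solver decomposes `K`'s sparsity pattern into connected
components (families) and batches equal-sized blocks through stacked
Cholesky factorizations, so a fit at n = 2,000 in 4-person families takes
milliseconds; a dense `K` degenerates to a single block and stays correct.

Stage 2 rank-inverse-normalizes the Stage-1 marginal residuals — Blom
offset `(r - 3/8)/(n + 1/4)`, average ranks for ties — standardizes the
quantiles by their own sample SD, multiplies by the residuals' sample SD
(n−1 denominator), and refits the identical model (variance components
re-estimated, not carried over).  The standardization step makes the
transformed outcome's SD equal the residual SD exactly, so effect sizes
from Stage-2 score tests stay in bp.  One consequence worth knowing: the
transform compresses outlying residuals, which slightly shrinks estimated
effects of very rare, large-effect variants — visible in the gene-based
power analysis below.

Score tests use the Stage-2 projection `P`: `U = g'Py`, `V = g'Pg`,
`chi2 = U²/V` against chi-square(1), `beta = U/V`, `se = V^{-1/2}`.
Missing genotypes are mean-imputed; monomorphic or fully
covariate-collinear variants (V ≈ 0) are flagged missing rather than
failing.  PVE is approximated as `chi2/(n - k)` with k the fixed-effect
count; the joint version is `U'V⁻¹U/(n - k)` over a variant set, which
accounts for score covariance and so never double-counts shared signal.
Both are validated against OLS partial-R² oracles on unrelated samples.

QC filters: pooled MAC >= 5, and the fraction of samples with genotype
depth < 10 strictly below 10% (a variant at exactly 10% is removed).

Conditional analysis runs per chromosome: the minimum-p variant below
5e-9 (ties broken by smaller p, larger |beta|, smaller coordinate) enters
the conditioning set, the conditioning genotypes are added as fixed effects
to *both* stages, and testing repeats until nothing crosses the threshold;
a user exclusion list stands in for manual variant-quality review.  The
joint model instead keeps the primary Stage-1 residuals and adds all
sentinels simultaneously to Stage 2, giving mutually adjusted effects used
for Cochran's Q heterogeneity (inverse-variance weights, chi-square with
strata − 1 df) and for polygenic trait scores.

## Gene-based tests

The deleteriousness mask admits stop gain/loss, start loss, transcript
ablation/amplification, splice acceptor/donor and frameshift consequences
outright, and missense variants with REVEL > 0.5, M-CAP "Damaging", or
CADD PHRED > 30.  Missing scores are non-qualifying for their criterion
(the OR of criteria reads naturally this way); unknown consequence strings
are a validation error.  Sets keep pooled MAF < 0.01 variants; genes below
cumulative MAC 5 are dropped.  Weights are the Beta(1, 25) density,
`25 (1 - MAF)^24`.

With `S` the weighted score vector and `Phi` its covariance under the null
fit, the burden statistic is `(1'S)²/(1'Phi 1)`; the adjusted SKAT
statistic is `||S - Phi 1 (1'S)/(1'Phi 1)||²` with null distribution the
eigenvalues of `Phi - Phi 1 1'Phi/(1'Phi 1)` — the two are asymptotically
independent (their covariance vanishes identically), so Fisher's method
(chi-square, 4 df) combines them.  Quadratic-form tails use Imhof's
characteristic-function integral evaluated on a phase-controlled grid
(step 0.1 radian of oscillation, truncated where the period-cancellation
bound falls below 1e-8; equal-eigenvalue cases reduce to scaled
chi-squares in closed form), accurate to ~1e-8 absolute against adaptive
quadrature and Monte Carlo oracles; the Liu moment-matching approximation
is the fallback and is flagged in the output.  Single-variant sets reduce
exactly to the single-variant score test with no SKAT component.

## Colocalization and polygenic scores

Wakefield log-ABFs are `0.5 log(1 - r) + 0.5 z² r` with
`r = W/(W + se²)` and prior effect SD `sqrt(W) = 0.15` (quantitative-trait
convention; configurable).  The five hypothesis sums use per-variant priors
p1 = p2 = 1e-4, p12 = 1e-5 and are normalized in log space.  PTS is
`sum_j dosage_ij beta_j` with effect alleles reconciled against the VCF
(exact ALT match, REF match flips, strand-ambiguous palindromic variants
rejected) and missing dosages imputed at twice the effect-allele frequency.

## Cohort simulation

Families are full sibships over two unobserved parents: founder genotypes
in Hardy-Weinberg proportions, Mendelian transmission, block-diagonal
relatedness (1 diagonal, 0.5 sibs).  The phenotype adds an intercept
(3,500 bp, a typical leukocyte TelSeq-scale TL), an age slope (−11 bp/year,
the scale seen in sequence-estimated TL), a sex effect (−40 bp), causal
dosage effects, a polygenic term with variance `h2/(1-h2)` times the mean
stratum residual variance, and stratum-specific Gaussian noise (defaults
450/550 bp).  Per-genotype depth is Poisson(38), matching ~38x coverage;
planted low-depth variants exercise the depth filter.  Not emulated:
linkage disequilibrium between cohort variants (each is drawn
independently; LD enters only through the AR(1) colocalization fixtures
and explicit proxy constructions in tests), assortative mating,
genotype-calling error.

Colocalization fixtures draw z-scores `z ~ N(effect_z * Sigma[:, c],
Sigma)` with AR(1) LD `Sigma_ij = ld_decay^|i-j|`; shared or distinct
causal indices give PPH4- or PPH3-dominated truth.

## Problem sizes and power design of the validation scenarios

The validation suite uses scaled-down but statistically faithful problem
sizes chosen once: calibration at n = 500 related samples x 2,000 null
variants; effect recovery (beta = −30 bp at MAF 0.3) at n = 2,000 over 50
replicates; sentinel discovery with two unlinked causal variants of
+/- ~200 bp, sized so each passes 5e-9 with a wide margin; batch recovery
at 100 samples x 1,000 bins x 3 factors over 50 replicates; 500 null genes
for gene-test calibration; 100 colocalization replicates.  The gene-based
*power* scenario (five −80 bp variants at MAF 0.005, n = 2,000, target
p < 1e-4 in >= 90% of replicates) was sized by a power computation:
Fisher-combining the burden p with a null SKAT component costs roughly two
orders of magnitude in p, and the rank-INT stage compresses the outlier
tails carrying rare-variant signal, so the scenario needs a burden
z near 8 — residual SDs of 90/110 bp with h2 = 0.2 provide that.

## Known limitations

* The PVE formula `chi2/(n - k)` is an approximation that ignores the
  effective sample-size reduction from relatedness; it is validated only
  against unrelated-sample oracles.
* The heteroskedastic REML becomes weakly identified when kinship is the
  identity (genetic and residual variance are confounded); fits remain
  well-defined through the information-matrix ridge, but the split between
  the two components is arbitrary there — only their sum is meaningful.
* Depth binning for alignments is an in-memory implementation intended for
  synthetic alignments and small files; production-scale depth extraction
  should use a dedicated tool and feed the bin TSV in.
* `coloc_abf` assumes one causal variant per trait in the window, as the
  ABF framework does; violations push mass toward PPH3.
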