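# telogene

Sequence-based telomere-length genetics: estimate telomere length (TL) from
whole-genome sequencing reads, remove technical batch effects learned from
genome-wide coverage, and run a fully adjusted two-stage linear mixed-model
association analysis — single-variant score tests, iterative conditional
sentinel discovery, joint models, cross-population heterogeneity,
deleterious rare-variant gene-based tests, colocalization posteriors and
polygenic trait scores.  A synthetic-data module generates every input with
known ground truth, so the whole chain is testable end to end.

It is aimed at statistical geneticists who want the analysis chain as a
reusable, tested library rather than a collection of one-off scripts.

## The methods

**TL estimation.** Telomeres are tandem arrays of TTAGGG.  With `tel` the
number of reads containing at least k = 12 non-overlapping copies of the
motif and `gc` the number of reads with GC content in [48%, 52%] (the repeat
itself is 50% GC, so this matches GC-dependent coverage artifacts),

    tl_bp = (tel / gc) * c

where c is the genomic length at matching GC divided by the number of
chromosome ends.

**Batch correction.** Mean depth in 1,000 bp bins genome-wide; drop bins
with mappability < 1, blacklist overlap, or off the autosomes; divide each
sample by its mean depth and center each bin; take a randomized truncated
SVD.  The left factors ("batch PCs") are latent technical axes; TL is
regressed on the leading components and the residuals (plus intercept, so
bp units and the mean are preserved) are the corrected phenotype.

**Association.** The model for corrected TL y with covariates X is

    y = X b + g + e,   g ~ N(0, sg2 K),   e_i ~ N(0, s2_{group(i)})

with K a sparse family relatedness matrix and one residual variance per
study/population group, fitted by average-information REML
(`TelomereLMM(...).fit()` returns a results object with `summary()`).  The
two-stage form rank-inverse-normalizes the Stage-1 marginal residuals (Blom
offset), rescales them to the original SD, and refits the identical model;
variants are then tested with score tests (U = g'Py, V = g'Pg,
chi2 = U^2/V, beta = U/V, PVE = chi2/(n-k)).  Sentinels are discovered by
per-chromosome iterative conditioning at p < 5e-9 and re-estimated jointly;
Cochran's Q measures effect heterogeneity across population strata.

**Gene-based tests.** Rare (MAF < 1%) loss-of-function and
predicted-damaging missense variants (REVEL > 0.5, M-CAP damaging, or CADD
\> 30), weighted by the Beta(1, 25) density at the MAF, tested with the
SMMAT hybrid: a burden score test plus a burden-adjusted SKAT quadratic
form (Davies tail probability, Liu fallback), combined by Fisher's method.

**Colocalization and scores.** Wakefield approximate Bayes factors from
beta/SE pairs give posterior probabilities PPH0–PPH4 for the five
colocalization hypotheses; polygenic trait scores are dosage-weighted sums
of joint effect sizes in bp.

## Worked example

```python
import numpy as np
from telogene import synthio, assoc
from telogene.lmm import TwoStageLMM

spec = synthio.CohortSimSpec(
    n_families=500, family_size=4, h2=0.4,
    causal_variants=((0.3, -30.0),), n_null_variants=10, seed=3)
cohort, genotypes, kinship = synthio.simulate_cohort(spec)

model = TwoStageLMM(cohort, "tl", ["age", "sex"], kinship, "group")
fit1, fit2 = model.fit()
print(f"heritability estimate: "
      f"{fit1.var_genetic / (fit1.var_genetic + fit1.var_residual_by_group.mean()):.3f}")
table = assoc.score_tests(fit2, genotypes)
print(table[["id", "maf", "beta", "se", "p"]].head(3).to_string(index=False))
```

prints

```
heritability estimate: 0.419
  id     maf       beta        se        p
var1 0.29550 -18.409589 24.780829 0.457544
var2 0.08725 -14.416159 39.719067 0.716640
var3 0.14575   1.508720 31.357809 0.961626
```

The heritability ratio recovers the simulated 0.4; `var1` is the planted
causal variant (beta −30 bp at MAF 0.3; this single draw of n = 2,000
estimates −18 ± 25, covering the truth — a −30 bp effect needs far more
than 2,000 samples to reach significance) and the remaining variants are
null.

A command-line interface mirrors the library:
`telogene simulate {reads,coverage,cohort,coloc}`, `telogene tl`,
`telogene batchpc`, `telogene assoc`, `telogene conditional`,
`telogene joint`, `telogene hetero`, `telogene genetest`, `telogene pts`,
`telogene coloc` — see `telogene --help`.

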