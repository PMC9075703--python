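"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator here is bit-reproducible under a fixed seed and emits the
same plain-text formats the analysis modules read (FASTQ, BED-like bin TSV,
VCF with per-genotype DP, phenotype TSV, kinship triplet TSV), so the whole
pipeline can be exercised end-to-end against known ground truth:

* reads with controllable telomeric-repeat content and GC mixture
  (:func:`simulate_reads`), with analytically computable expected telomeric
  and GC-window read counts;
* coverage-bin matrices with planted low-rank batch factors
  (:func:`simulate_coverage`) that can also be made to contaminate TL
  (:func:`contaminate_tl`);
* family-structured cohorts with stratum-specific residual variances,
  a polygenic term of chosen heritability, and causal variants of known
  effect in bp per allele (:func:`simulate_cohort`);
* paired GWAS/eQTL summary statistics with AR(1) linkage disequilibrium and
  a shared or distinct causal variant (:func:`simulate_coloc_pair`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .batchpc import BinDepthMatrix
from .data import GenotypeBlock, KinshipMatrix
from .telseq import TELOMERE_MOTIF

# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class ReadSimSpec:
    """Specification for a simulated whole-genome read set.

    ``true_tl`` is the telomere length per chromosome end in bp.  The genome
    is abstracted to a total size and a number of chromosome ends; reads fall
    on the telomeric tract with probability
    ``true_tl * n_chrom_ends / genome_size`` (scaled by ``batch_shift``,
    a multiplicative technical bias on telomeric-read recovery).  Background
    reads draw their per-base GC probability from ``gc_mixture``, a list of
    (gc_fraction, weight) components.  Telomeric reads are perfect TTAGGG
    arrays with per-base substitution noise at rate 1 - telomere_purity.
    """

    true_tl: float
    n_reads: int
    read_length: int = 151
    gc_mixture: tuple[tuple[float, float], ...] = ((0.41, 1.0),)
    telomere_purity: float = 1.0
    batch_shift: float = 1.0
    genome_size: float = 1_000_000.0
    n_chrom_ends: int = 46
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_tl < 0:
            raise ValueError("true_tl must be >= 0")
        if self.read_length < 6:
            raise ValueError("read_length must be >= 6")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not 0 <= self.telomere_purity <= 1:
            raise ValueError("telomere_purity must be in [0, 1]")
        if self.batch_shift < 0:
            raise ValueError("batch_shift must be >= 0")
        w = sum(w for _, w in self.gc_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"gc_mixture weights sum to {w}, expected 1")
        if any(not 0 <= g <= 1 for g, _ in self.gc_mixture):
            raise ValueError("gc fractions must be in [0, 1]")
        if self.telomere_fraction > 1:
            raise ValueError("telomeric fraction exceeds 1; check true_tl, "
                             "batch_shift and genome_size")

    @property
    def telomere_fraction(self) -> float:
        """Probability that a read is telomeric (includes batch_shift)."""
        return self.true_tl * self.n_chrom_ends / self.genome_size * self.batch_shift

    def expected_counts(self, k: int = 12,
                        gc_window: tuple[float, float] = (0.48, 0.52),
                        ) -> dict[str, float]:
        """Analytic expectations for the TL estimator on this spec.

        Exact for ``telomere_purity = 1`` (all telomeric reads carry the
        maximal repeat count).  Returns expected telomeric reads, expected
        GC-window reads, the matched length constant ``c`` and the implied
        expected TL estimate.
        """
        lo, hi = gc_window
        L = self.read_length
        p_tel = self.telomere_fraction
        # background GC-window probability: per-base GC is exact, so the
        # read's GC count is Binomial(L, gc) within each mixture component
        klo = int(np.ceil(lo * L - 1e-9))
        khi = int(np.floor(hi * L + 1e-9))
        p_win_bg = sum(
            w * (stats.binom.cdf(khi, L, g) - stats.binom.cdf(klo - 1, L, g))
            for g, w in self.gc_mixture)
        # telomeric reads: GC content of a length-L window of the periodic
        # motif depends only on the phase offset
        tandem = TELOMERE_MOTIF * (L // 6 + 2)
        p_win_tel = np.mean([
            lo <= _gc(tandem[o:o + L]) <= hi for o in range(6)])
        n_bg = self.n_reads * (1 - p_tel)
        e_tel = self.n_reads * p_tel
        e_gc = n_bg * p_win_bg + e_tel * p_win_tel
        # length constant: genomic length at matching GC over chromosome ends
        tel_total = self.true_tl * self.n_chrom_ends
        c = (p_win_bg * (self.genome_size - tel_total)
             + p_win_tel * tel_total) / self.n_chrom_ends
        e_tl = np.inf if e_gc == 0 else e_tel / e_gc * c
        return {"tel_reads": e_tel, "gc_reads": e_gc,
                "length_constant_c": c, "tl_bp": e_tl}


def _gc(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s)


@dataclass
class ReadSet:
    """Simulated reads with names, ready to write as FASTQ."""

    names: list[str]
    reads: list[str]
    spec: ReadSimSpec | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def write_fastq(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.reads):
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


_BASES = np.array(list("ACGT"))


def simulate_reads(spec: ReadSimSpec) -> ReadSet:
    """Generate a read set according to ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length
    is_tel = rng.random(spec.n_reads) < spec.telomere_fraction
    n_tel = int(is_tel.sum())
    reads: list[str] = [""] * spec.n_reads

    # telomeric reads: perfect tandem array at a random phase, then per-base
    # substitutions at rate (1 - purity) to stress the repeat detector
    tandem = TELOMERE_MOTIF * (L // 6 + 2)
    tel_positions = np.flatnonzero(is_tel)
    offsets = rng.integers(0, 6, size=n_tel)
    sub_rate = 1.0 - spec.telomere_purity
    for idx, off in zip(tel_positions, offsets):
        seq = np.array(list(tandem[off:off + L]))
        if sub_rate > 0:
            mask = rng.random(L) < sub_rate
            if mask.any():
                # substitute with a uniformly random different base
                shift = rng.integers(1, 4, size=int(mask.sum()))
                base_idx = np.searchsorted(_BASES, seq[mask])
                seq[mask] = _BASES[(base_idx + shift) % 4]
        reads[idx] = "".join(seq)

    # background reads: per-base GC probability from the mixture
    bg_positions = np.flatnonzero(~is_tel)
    if bg_positions.size:
        gcs = np.array([g for g, _ in spec.gc_mixture])
        ws = np.array([w for _, w in spec.gc_mixture])
        comp = rng.choice(len(gcs), size=bg_positions.size, p=ws / ws.sum())
        for idx, ci in zip(bg_positions, comp):
            g = gcs[ci]
            is_gc = rng.random(L) < g
            picks = rng.integers(0, 2, size=L)
            seq = np.where(is_gc, np.where(picks == 0, "G", "C"),
                           np.where(picks == 0, "A", "T"))
            reads[idx] = "".join(seq)

    names = [f"read{i:07d}" for i in range(spec.n_reads)]
    return ReadSet(names=names, reads=reads, spec=spec)


# ---------------------------------------------------------------------------
# coverage


def simulate_coverage(n_samples: int, n_bins: int, n_factors: int,
                      loading_scale: float = 3.0, noise_sd: float = 0.5,
                      seed: int = 0, *, baseline_depth: float = 38.0,
                      frac_blacklist: float = 0.05, frac_lowmap: float = 0.05,
                      frac_chrx: float = 0.05,
                      bin_size: int = 1000,
                      ) -> tuple[BinDepthMatrix, np.ndarray]:
    """Coverage-bin matrix with planted low-rank batch structure.

    depth = baseline * (1 + factor structure) + noise, where the factor
    structure is ``scores @ loadings`` with per-sample factor scores ~ N(0,1)
    and loadings scaled so one factor SD moves depth by ``loading_scale``
    (depth units).  A fraction of bins is planted with blacklist flags,
    mappability < 1 or a chrX label so the filter stage is exercised; the
    planted bins carry no factor signal loss (filters only drop rows of
    metadata).  Returns the matrix and the true factor scores for recovery
    tests.
    """
    if n_factors >= min(n_samples, n_bins):
        raise ValueError("n_factors must be < min(n_samples, n_bins)")
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_samples, n_factors))
    loadings = rng.standard_normal((n_factors, n_bins))
    if n_factors:
        loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
        loadings *= np.sqrt(n_bins)  # unit variance per bin on average
    structure = (loading_scale / baseline_depth) * (factors @ loadings) \
        if n_factors else np.zeros((n_samples, n_bins))
    depths = baseline_depth * (1.0 + structure)
    if noise_sd > 0:
        depths = depths + rng.normal(0.0, noise_sd, size=depths.shape)
    depths = np.clip(depths, 0.0, None)

    n_bad = int(round(frac_blacklist * n_bins))
    n_lowmap = int(round(frac_lowmap * n_bins))
    n_x = int(round(frac_chrx * n_bins))
    flags = np.zeros(n_bins, dtype=bool)
    mapp = np.ones(n_bins)
    chrom = np.array(["chr1"] * n_bins, dtype=object)
    bad = rng.choice(n_bins, size=n_bad + n_lowmap + n_x, replace=False)
    flags[bad[:n_bad]] = True
    mapp[bad[n_bad:n_bad + n_lowmap]] = rng.uniform(0.5, 0.99, size=n_lowmap)
    chrom[bad[n_bad + n_lowmap:]] = "chrX"
    starts = np.arange(n_bins) * bin_size
    bins = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + bin_size,
        "mappability": mapp, "blacklist": flags,
    })
    samples = [f"s{i + 1}" for i in range(n_samples)]
    return BinDepthMatrix(samples=samples, bins=bins, depths=depths), factors


def contaminate_tl(tl_true: np.ndarray, factors: np.ndarray,
                   gamma: np.ndarray) -> np.ndarray:
    """Add batch-factor contamination to a true TL vector (bp).

    ``gamma`` gives the bp shift per factor SD, emulating technical factors
    that bias both genome-wide coverage and the telomeric read ratio.
    """
    return np.asarray(tl_true, float) + np.asarray(factors, float) @ np.asarray(gamma, float)


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class CohortSimSpec:
    """Specification for a family-structured cohort simulation.

    Families are full sibships sharing two unobserved parents, so the
    relatedness matrix is block diagonal with unit diagonal and 0.5 between
    sibs.  The phenotype (TL in bp) is

        tl = intercept + age_slope * age + sex_effect * sex
             + sum_j beta_j * dosage_j + polygenic + stratum noise

    with the polygenic variance set from ``h2`` relative to the mean stratum
    residual variance, and stratum-specific residual SDs in bp.
    """

    n_families: int
    family_size: int = 4
    n_strata: int = 2
    stratum_residual_sd: tuple[float, ...] = (450.0, 550.0)
    h2: float = 0.4
    causal_variants: tuple[tuple[float, float], ...] = ()
    age_slope: float = -11.0
    sex_effect: float = -40.0
    intercept: float = 3500.0
    n_null_variants: int = 0
    mean_dp: float = 38.0
    n_low_dp_variants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2 < 1:
            raise ValueError("h2 must be in [0, 1)")
        if len(self.stratum_residual_sd) != self.n_strata:
            raise ValueError("need one residual SD per stratum")
        if any(s <= 0 for s in self.stratum_residual_sd):
            raise ValueError("residual SDs must be > 0")
        for maf, _ in self.causal_variants:
            if not 0 < maf <= 0.5:
                raise ValueError(f"MAF {maf} outside (0, 0.5]")
        if self.n_families < 1 or self.family_size < 1:
            raise ValueError("n_families and family_size must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_families * self.family_size


def _family_genotypes(rng: np.random.Generator, maf: float,
                      n_families: int, family_size: int) -> np.ndarray:
    """HWE founder genotypes with Mendelian transmission to sibships."""
    if family_size == 1:
        return rng.binomial(2, maf, size=n_families).astype(float)
    parents = rng.binomial(2, maf, size=(n_families, 2)).astype(float)
    # each sib receives one allele from each parent
    p_transmit = parents / 2.0
    geno = (rng.random((n_families, family_size)) < p_transmit[:, [0]]).astype(float)
    geno += (rng.random((n_families, family_size)) < p_transmit[:, [1]])
    return geno.reshape(-1)


def simulate_cohort(spec: CohortSimSpec,
                    ) -> tuple[pd.DataFrame, GenotypeBlock, KinshipMatrix]:
    """Simulate (phenotype table, genotypes, kinship) per ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    fs = spec.family_size
    samples = [f"id{i + 1:06d}" for i in range(n)]
    family = np.repeat(np.arange(spec.n_families), fs)

    # kinship: block diagonal, 1 on the diagonal, 0.5 between full sibs
    from scipy import sparse
    block = np.full((fs, fs), 0.5)
    np.fill_diagonal(block, 1.0)
    kin = sparse.block_diag([block] * spec.n_families, format="csr")
    kinship = KinshipMatrix(samples=samples, matrix=kin)

    # genotypes
    specs = list(spec.causal_variants) + [
        (float(maf), 0.0) for maf in rng.uniform(0.05, 0.5, spec.n_null_variants)]
    m = len(specs)
    dosages = np.empty((n, m))
    betas = np.empty(m)
    for j, (maf, beta) in enumerate(specs):
        dosages[:, j] = _family_genotypes(rng, maf, spec.n_families, fs)
        betas[j] = beta
    variants = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, m + 1) * 10_000,
        "id": [f"var{j + 1}" for j in range(m)],
        "ref": "A", "alt": "G",
    }, columns=["chrom", "pos", "id", "ref", "alt"])

    dp = rng.poisson(spec.mean_dp, size=(n, m)).astype(float)
    for j in range(min(spec.n_low_dp_variants, m)):
        low = rng.choice(n, size=max(1, int(0.12 * n)), replace=False)
        dp[low, j] = rng.poisson(5.0, size=low.size)
    block_geno = GenotypeBlock(samples=samples, variants=variants,
                               dosages=dosages, dp=dp)

    # covariates and strata (stratum constant within family)
    age = rng.uniform(20.0, 70.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    stratum = (family % spec.n_strata)
    resid_sd = np.asarray(spec.stratum_residual_sd)[stratum]

    # polygenic term: a ~ N(0, sg2 * K), drawn per family block
    mean_res_var = float(np.mean(np.square(spec.stratum_residual_sd)))
    sg2 = spec.h2 / (1.0 - spec.h2) * mean_res_var
    if sg2 > 0:
        chol = np.linalg.cholesky(block)
        z = rng.standard_normal((spec.n_families, fs))
        poly = np.sqrt(sg2) * (z @ chol.T).reshape(-1)
    else:
        poly = np.zeros(n)

    tl = (spec.intercept + spec.age_slope * age + spec.sex_effect * sex
          + dosages @ betas + poly + rng.normal(0.0, resid_sd))

    cohort = pd.DataFrame({
        "sample": samples, "family": family, "age": age, "sex": sex,
        "group": [f"stratum{s + 1}" for s in stratum],
        "tl": tl,
    })
    return cohort, block_geno, kinship


def write_phenotypes(cohort: pd.DataFrame, path: str) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# colocalization fixtures


def simulate_coloc_pair(n_variants: int, ld_decay: float = 0.9,
                        shared: bool = True, effect_z: float = 8.0,
                        seed: int = 0, *, n_samples: int = 10_000,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two summary-statistic tables over a common AR(1) LD structure.

    Z-scores follow z ~ N(effect_z * Sigma[:, causal], Sigma) with
    Sigma_ij = ld_decay^|i-j|.  If ``shared`` both traits load on the same
    causal variant; otherwise two variants far apart (low LD) are used.
    Betas and SEs are on a per-allele scale with SE = 1/sqrt(n_samples).
    """
    if n_variants < 2:
        raise ValueError("n_variants must be >= 2")
    if not 0 <= ld_decay < 1:
        raise ValueError("ld_decay must be in [0, 1)")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_variants)
    sigma = ld_decay ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(n_variants))
    c1 = n_variants // 2
    c2 = c1 if shared else n_variants // 10
    tables = []
    for causal in (c1, c2):
        mean = effect_z * sigma[:, causal]
        z = mean + chol @ rng.standard_normal(n_variants)
        se = np.full(n_variants, 1.0 / np.sqrt(n_samples))
        tables.append(pd.DataFrame({
            "variant": [f"v{i + 1}" for i in idx],
            "beta": z * se, "se": se,
        }))
    return tables[0], tables[1]
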