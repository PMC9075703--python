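"""Core data containers: genotype blocks, kinship matrices, cohort tables.

A :class:`GenotypeBlock` holds an (n samples x m variants) dosage matrix with
per-variant metadata and optional per-genotype sequencing depth (DP), backed
by plain VCF v4.2 for interchange.  A :class:`KinshipMatrix` is the symmetric
PSD relatedness matrix used as the covariance of the polygenic random effect
(unit diagonal for non-inbred samples, i.e. twice the kinship coefficient).
Cohort phenotype/covariate tables are ordinary pandas DataFrames with a
``sample`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from scipy import sparse

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypeBlock:
    """Dosage matrix (samples x variants) with variant metadata.

    ``dosages`` holds alternate-allele counts in {0,1,2} with NaN for missing
    genotypes; ``dp`` holds per-genotype read depth (same shape) or None.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} samples vs {n} dosage rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variants vs {m} columns")
        if self.dp is not None and self.dp.shape != (n, m):
            raise ValueError("dp shape does not match dosages")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_counts(self) -> np.ndarray:
        """Alternate-allele count per variant over non-missing genotypes."""
        return np.nansum(self.dosages, axis=0)

    def mac(self) -> np.ndarray:
        """Pooled minor allele count per variant."""
        called = 2 * np.sum(~np.isnan(self.dosages), axis=0)
        ac = self.allele_counts()
        return np.minimum(ac, called - ac)

    def maf(self) -> np.ndarray:
        """Pooled minor allele frequency per variant."""
        called = 2 * np.sum(~np.isnan(self.dosages), axis=0)
        with np.errstate(invalid="ignore"):
            af = self.allele_counts() / called
        return np.minimum(af, 1.0 - af)

    def subset_variants(self, index) -> "GenotypeBlock":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeBlock(
            samples=self.samples,
            variants=self.variants.iloc[index],
            dosages=self.dosages[:, index],
            dp=None if self.dp is None else self.dp[:, index],
        )

    def subset_samples(self, keep: list[str]) -> "GenotypeBlock":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in keep])
        return GenotypeBlock(
            samples=list(keep),
            variants=self.variants,
            dosages=self.dosages[idx],
            dp=None if self.dp is None else self.dp[idx],
        )

    # ------------------------------------------------------------------ I/O

    def write_vcf(self, path: str) -> None:
        """Write a plain-text VCF v4.2 with GT and DP fields."""
        var = self.variants
        contigs = list(dict.fromkeys(var["chrom"].astype(str)))
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                     'Description="Read depth">\n')
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            for j in range(self.n_variants):
                row = var.iloc[j]
                fields = [str(row["chrom"]), str(int(row["pos"])),
                          str(row["id"]), str(row["ref"]), str(row["alt"]),
                          ".", "PASS", ".", "GT:DP"]
                col = self.dosages[:, j]
                dpc = self.dp[:, j] if self.dp is not None else None
                for i in range(self.n_samples):
                    gt = "./." if np.isnan(col[i]) else gt_codes[col[i]]
                    dp = "." if dpc is None else str(int(dpc[i]))
                    fields.append(f"{gt}:{dp}")
                fh.write("\t".join(fields) + "\n")

    @classmethod
    def from_vcf(cls, path: str) -> "GenotypeBlock":
        """Load a VCF (GT required, DP optional) into a GenotypeBlock."""
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            meta, dos_cols, dp_cols = [], [], []
            for rec in vf:
                meta.append({
                    "chrom": rec.chrom, "pos": rec.pos,
                    "id": rec.id or ".",
                    "ref": rec.ref, "alt": rec.alts[0] if rec.alts else ".",
                })
                dos = np.full(len(samples), np.nan)
                dpv = np.full(len(samples), np.nan)
                for i, s in enumerate(samples):
                    call = rec.samples[s]
                    alleles = call.get("GT")
                    if alleles is not None and None not in alleles:
                        dos[i] = float(sum(alleles))
                    dp = call.get("DP")
                    if dp is not None:
                        dpv[i] = dp
                dos_cols.append(dos)
                dp_cols.append(dpv)
        dosages = np.column_stack(dos_cols) if dos_cols else np.empty((len(samples), 0))
        dp = np.column_stack(dp_cols) if dp_cols else None
        if dp is not None and np.all(np.isnan(dp)):
            dp = None
        return cls(samples=samples, variants=pd.DataFrame(meta, columns=VARIANT_COLUMNS),
                   dosages=dosages, dp=dp)


@dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix with sample labels.

    Stored dense or scipy-sparse; entries are twice the kinship coefficient
    (1.0 on the diagonal for non-inbred individuals, 0.5 for full sibs or
    parent-offspring pairs).
    """

    samples: list[str]
    matrix: np.ndarray | sparse.spmatrix = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.matrix.shape != (n, n):
            raise ValueError("kinship matrix shape does not match samples")

    def to_dense(self) -> np.ndarray:
        if sparse.issparse(self.matrix):
            return self.matrix.toarray()
        return np.asarray(self.matrix, dtype=float)

    def to_sparse(self) -> sparse.csr_matrix:
        if sparse.issparse(self.matrix):
            return self.matrix.tocsr()
        return sparse.csr_matrix(self.matrix)

    def reorder(self, samples: list[str]) -> "KinshipMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in samples])
        m = self.to_sparse()[idx][:, idx]
        return KinshipMatrix(samples=list(samples), matrix=m)

    def write_triplets(self, path: str) -> None:
        """Write non-zero entries (upper triangle incl. diagonal) as TSV."""
        coo = self.to_sparse().tocoo()
        with open(path, "w") as fh:
            fh.write("sample_i\tsample_j\tvalue\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                if i <= j and v != 0:
                    fh.write(f"{self.samples[i]}\t{self.samples[j]}\t{v:.10g}\n")

    @classmethod
    def from_triplets(cls, path: str) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = list(dict.fromkeys(pd.concat([df["sample_i"], df["sample_j"]])))
        pos = {s: i for i, s in enumerate(labels)}
        n = len(labels)
        mat = sparse.lil_matrix((n, n))
        for si, sj, v in zip(df["sample_i"], df["sample_j"], df["value"]):
            i, j = pos[si], pos[sj]
            mat[i, j] = v
            mat[j, i] = v
        return cls(samples=labels, matrix=mat.tocsr())
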