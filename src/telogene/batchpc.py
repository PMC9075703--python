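"""Batch-effect correction of telomere-length estimates from coverage bins.

Sequencing batch, library preparation and flow cell all leave fingerprints in
the genome-wide coverage profile of a sample.  Averaging depth in fixed
1,000 bp bins, filtering out bins that are unreliable (imperfect mappability,
structural-variant/CNV blacklist, sex chromosomes), normalizing within sample
and taking a truncated SVD across samples yields "batch principal
components" (bPCs): latent technical factors.  Regressing the TL estimate on
the leading bPCs and keeping the residuals (plus the intercept, so the bp
scale and mean are preserved) removes the technical contamination.

The truncated SVD is computed with a randomized range finder (Gaussian
sketch, power iterations, orthonormalization), which scales to hundreds of
thousands of bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .telseq import DegenerateInputError

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}

BIN_COLUMNS = ["chrom", "start", "end", "mappability", "blacklist"]


@dataclass
class BinDepthMatrix:
    """Samples x genomic-bins mean-depth matrix with bin metadata.

    ``bins`` carries chrom, start (0-based), end (half-open), mappability in
    [0, 1] and a boolean blacklist flag per bin.
    """

    samples: list[str]
    bins: pd.DataFrame
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.shape != (len(self.samples), len(self.bins)):
            raise ValueError("depths shape must be (n_samples, n_bins)")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")
        dup = self.bins.duplicated(subset=["chrom", "start"])
        if dup.any():
            raise ValueError("duplicate (chrom, start) bins")
        self.bins = self.bins.reset_index(drop=True)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def write_tsv(self, path: str) -> None:
        """BED-like TSV: chrom start end mappability blacklist depth_s1.."""
        out = self.bins[BIN_COLUMNS].copy()
        out["blacklist"] = out["blacklist"].astype(int)
        for i, s in enumerate(self.samples):
            out[f"depth_{s}"] = self.depths[i]
        out.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str) -> "BinDepthMatrix":
        df = pd.read_csv(path, sep="\t")
        depth_cols = [c for c in df.columns if c.startswith("depth_")]
        samples = [c[len("depth_"):] for c in depth_cols]
        bins = df[BIN_COLUMNS].copy()
        bins["blacklist"] = bins["blacklist"].astype(bool)
        return cls(samples=samples, bins=bins,
                   depths=df[depth_cols].to_numpy().T)


@dataclass
class BatchPCs:
    """Batch principal components: per-sample scores and singular values."""

    samples: list[str]
    scores: np.ndarray          # samples x n_components
    singular_values: np.ndarray  # descending
    components: np.ndarray      # n_components x bins (right singular vectors)
    seed: int | None = None
    oversampling: int = 10
    power_iters: int = 2

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def write_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.scores, columns=[
            f"bPC{i + 1}" for i in range(self.n_components)])
        df.insert(0, "sample", self.samples)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def bin_depths(alignments: dict[str, list[tuple[str, int, int]]],
               bins: pd.DataFrame, bin_size: int = 1000) -> BinDepthMatrix:
    """Mean depth per bin from alignment records.

    ``alignments`` maps sample -> list of (chrom, start, length) records
    (0-based starts).  Each bin's mean depth is the total number of aligned
    bases overlapping the bin divided by the bin width; a read straddling a
    bin boundary contributes proportionally to both bins.
    """
    bin_index: dict[str, dict[int, int]] = {}
    for j, row in bins.iterrows():
        bin_index.setdefault(str(row["chrom"]), {})[int(row["start"])] = j
    widths = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    samples = list(alignments)
    depths = np.zeros((len(samples), len(bins)))
    for i, sample in enumerate(samples):
        for chrom, start, length in alignments[sample]:
            end = start + length
            first = (start // bin_size) * bin_size
            for bstart in range(first, end, bin_size):
                j = bin_index.get(str(chrom), {}).get(bstart)
                if j is None:
                    continue
                overlap = min(end, bstart + bin_size) - max(start, bstart)
                depths[i, j] += overlap
    depths /= widths
    return BinDepthMatrix(samples=samples, bins=bins, depths=depths)


def filter_bins(m: BinDepthMatrix) -> BinDepthMatrix:
    """Keep autosomal bins with mappability exactly 1.0 and no blacklist flag."""
    b = m.bins
    keep = (
        b["chrom"].astype(str).isin(AUTOSOMES)
        & (b["mappability"] >= 1.0)
        & ~b["blacklist"].astype(bool)
    ).to_numpy()
    if not keep.any():
        raise DegenerateInputError("all bins removed by filtering")
    return BinDepthMatrix(samples=m.samples, bins=b.loc[keep],
                          depths=m.depths[:, keep])


def normalize_bins(m: BinDepthMatrix) -> np.ndarray:
    """Within-sample normalization then per-bin centering.

    Each sample's row is divided by its own mean depth over the retained
    bins (making rows scale-free), then every bin column is centered to mean
    zero across samples (so components are orthogonal to the grand mean).
    """
    row_means = m.depths.mean(axis=1)
    zero = np.flatnonzero(row_means <= 0)
    if zero.size:
        names = [m.samples[i] for i in zero[:5]]
        raise ValueError(f"samples with zero mean depth: {names}")
    x = m.depths / row_means[:, None]
    return x - x.mean(axis=0, keepdims=True)


def randomized_svd(x: np.ndarray, n_components: int, *,
                   oversampling: int = 10, power_iters: int = 2,
                   seed: int = 0,
                   samples: list[str] | None = None) -> BatchPCs:
    """Truncated SVD via a Gaussian randomized range finder.

    Sketch Y = X Omega with Omega Gaussian (n_components + oversampling
    columns), refine the range with ``power_iters`` power iterations
    (orthonormalizing at each step for stability), project X onto the range
    and take its exact SVD.  Deterministic for a fixed ``seed``.
    """
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    k = n_components
    if k < 1:
        raise ValueError("n_components must be >= 1")
    if k + oversampling > min(n, m):
        if k > min(n, m):
            raise ValueError(
                f"n_components={k} exceeds min dimension {min(n, m)}")
        oversampling = min(n, m) - k
    rng = np.random.default_rng(seed)
    omega = rng.standard_normal((m, k + oversampling))
    q, _ = np.linalg.qr(x @ omega)
    for _ in range(power_iters):
        q, _ = np.linalg.qr(x.T @ q)
        q, _ = np.linalg.qr(x @ q)
    b = q.T @ x
    u_b, s, vt = np.linalg.svd(b, full_matrices=False)
    u = q @ u_b
    # scores U * S: exactly orthogonal, and exactly mean-zero when X's
    # columns are centered (the range basis stays orthogonal to the ones
    # vector), which residualize_tl relies on for mean preservation
    scores = u[:, :k] * s[:k]
    return BatchPCs(
        samples=samples if samples is not None else [f"s{i}" for i in range(n)],
        scores=scores, singular_values=s[:k], components=vt[:k],
        seed=seed, oversampling=oversampling, power_iters=power_iters)


def fit_batch_pcs(m: BinDepthMatrix, n_components: int = 200, *,
                  oversampling: int = 10, power_iters: int = 2,
                  seed: int = 0) -> BatchPCs:
    """filter -> normalize -> randomized SVD convenience pipeline."""
    filtered = filter_bins(m)
    x = normalize_bins(filtered)
    n_components = min(n_components, min(x.shape) - 1)
    return randomized_svd(x, n_components, oversampling=oversampling,
                          power_iters=power_iters, seed=seed,
                          samples=m.samples)


def residualize_tl(tl: np.ndarray, pcs: BatchPCs,
                   n_components: int | None = None) -> np.ndarray:
    """Remove the leading bPCs from TL by linear regression.

    Returns residuals plus the fitted intercept, keeping units (bp) and —
    because bPC scores are exactly mean-zero — the sample mean of TL.
    ``n_components=0`` returns the input unchanged.
    """
    tl = np.asarray(tl, dtype=float)
    if tl.shape[0] != pcs.scores.shape[0]:
        raise ValueError(
            f"{tl.shape[0]} TL values vs {pcs.scores.shape[0]} score rows")
    if n_components is None:
        n_components = pcs.n_components
    if n_components > pcs.n_components:
        raise ValueError(
            f"requested {n_components} components, only {pcs.n_components} fitted")
    if n_components == 0:
        return tl.copy()
    z = np.column_stack([np.ones_like(tl), pcs.scores[:, :n_components]])
    coef, *_ = np.linalg.lstsq(z, tl, rcond=None)
    resid = tl - z @ coef
    return resid + coef[0]


def component_diagnostics(tl: np.ndarray, pcs: BatchPCs,
                          references: dict[str, np.ndarray] | None = None,
                          labels: dict[str, np.ndarray] | None = None,
                          grid: list[int] = (0, 10, 50, 100, 200),
                          ) -> pd.DataFrame:
    """Residual diagnostics over a grid of component counts.

    For each grid value the TL is residualized on that many bPCs, and the
    table reports the Pearson correlation of the residuals with each named
    reference vector (e.g. an orthogonal lab measurement, or age) and the
    one-way between-group R-squared for each categorical label (e.g.
    sequencing plate).  This table is the instrument for choosing how many
    components to remove.
    """
    references = references or {}
    labels = labels or {}
    if not references and not labels:
        raise ValueError("supply at least one reference vector or label")
    rows = []
    for k in grid:
        if k > pcs.n_components:
            continue
        adj = residualize_tl(tl, pcs, k)
        row: dict[str, float] = {"n_components": k}
        for name, ref in references.items():
            ref = np.asarray(ref, dtype=float)
            if np.std(ref) == 0 or np.std(adj) == 0:
                row[f"corr_{name}"] = np.nan
            else:
                row[f"corr_{name}"] = float(np.corrcoef(adj, ref)[0, 1])
        for name, lab in labels.items():
            row[f"r2_{name}"] = group_r2(adj, np.asarray(lab))
        rows.append(row)
    return pd.DataFrame(rows)


def group_r2(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA between-group R^2 (variance explained by a label)."""
    values = np.asarray(values, dtype=float)
    grand = values.mean()
    sst = np.sum((values - grand) ** 2)
    if sst == 0:
        return 0.0
    ssb = 0.0
    for g in np.unique(groups):
        sel = values[groups == g]
        ssb += sel.size * (sel.mean() - grand) ** 2
    return float(ssb / sst)
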