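"""Polygenic trait scores and Bayesian colocalization posteriors.

The polygenic trait score (PTS) is the dosage-weighted sum of jointly
estimated sentinel effect sizes, in bp of telomere length.  Colocalization
of a GWAS signal with an eQTL signal is assessed with per-variant Wakefield
approximate Bayes factors and the standard five-hypothesis posterior
decomposition (no signal; trait-1 only; trait-2 only; two distinct causal
variants; one shared causal variant), with per-variant priors
p1 = p2 = 1e-4 and p12 = 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .data import GenotypeBlock

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def compute_pts(block: GenotypeBlock, effects: pd.DataFrame) -> np.ndarray:
    """Per-sample polygenic trait score in bp.

    ``effects`` needs columns variant, effect_allele, beta (bp per effect
    allele).  Effect alleles are reconciled against the VCF alleles: an
    exact match to ALT uses the dosage directly, a match to REF flips it
    (dosage of the effect allele is 2 - dosage); strand-ambiguous
    palindromic variants and unreconcilable alleles raise an error naming
    the variant.  Missing dosages are imputed as twice the effect-allele
    frequency.
    """
    var = block.variants.set_index("id")
    pts = np.zeros(block.n_samples)
    for _, row in effects.iterrows():
        vid = str(row["variant"])
        if vid not in var.index:
            raise KeyError(f"variant {vid} not present in genotype block")
        ref = str(var.loc[vid, "ref"]).upper()
        alt = str(var.loc[vid, "alt"]).upper()
        ea = str(row["effect_allele"]).upper()
        if (ref, alt) in _PALINDROMIC:
            raise ValueError(
                f"variant {vid} is strand-ambiguous (palindromic {ref}/{alt})")
        j = block.variants.index[block.variants["id"] == vid][0]
        dos = block.dosages[:, j]
        if ea == alt:
            eff_dos = dos
        elif ea == ref:
            eff_dos = 2.0 - dos
        else:
            raise ValueError(
                f"effect allele {ea} for {vid} matches neither REF={ref} "
                f"nor ALT={alt}")
        eaf = np.nanmean(eff_dos) / 2.0
        eff_dos = np.where(np.isnan(eff_dos), 2.0 * eaf, eff_dos)
        pts += eff_dos * float(row["beta"])
    return pts


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_variants: int
    p1: float
    p2: float
    p12: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2,
                         self.pph3, self.pph4])


def _log_abf(beta: np.ndarray, se: np.ndarray, sd_prior: float) -> np.ndarray:
    """Log Wakefield approximate Bayes factor per variant."""
    if np.any(se <= 0):
        raise ValueError("standard errors must be > 0")
    v = se ** 2
    w = sd_prior ** 2
    r = w / (w + v)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log1p(-r) + z2 * r)


def coloc_abf(stats1: pd.DataFrame, stats2: pd.DataFrame,
              p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
              sd_prior: float = 0.15,
              variant_col: str = "variant") -> ColocResult:
    """Approximate-Bayes-factor colocalization of two association signals.

    Both tables need columns ``variant``, ``beta``, ``se``; the analysis
    runs on their shared variants (at least two required).  ``sd_prior`` is
    the prior SD of the standardized effect at a causal variant (default
    0.15, the quantitative-trait convention).
    """
    merged = stats1.merge(stats2, on=variant_col, suffixes=("_1", "_2"))
    if len(merged) < 2:
        raise ValueError("need at least 2 overlapping variants")
    l1 = _log_abf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(),
                  sd_prior)
    l2 = _log_abf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(),
                  sd_prior)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over i != j of ABF1_i ABF2_j, in log space
    inner = s12 - s1 - s2
    log_h3_sum = s1 + s2 + (np.log1p(-np.exp(inner))
                            if inner < -1e-12 else -np.inf)
    log_post = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + log_h3_sum,
        np.log(p12) + s12,
    ])
    post = np.exp(log_post - logsumexp(log_post))
    post /= post.sum()
    return ColocResult(*post, n_variants=len(merged), p1=p1, p2=p2, p12=p12)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float


def welch_pts_compare(pts_a: np.ndarray, pts_b: np.ndarray) -> WelchResult:
    """Welch's unequal-variance two-sample t test with Satterthwaite df."""
    a = np.asarray(pts_a, dtype=float)
    b = np.asarray(pts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0,
                               a.mean(), b.mean(), 0.0, 0.0)
        raise ValueError("zero variance in both groups")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p), float(a.mean()),
                       float(b.mean()), float(np.sqrt(va)), float(np.sqrt(vb)))
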