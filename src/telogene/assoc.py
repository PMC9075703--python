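"""Single-variant association testing on the two-stage mixed-model fit.

Variants are tested with score tests against the Stage-2 null fit: with
P the projection onto the residual space of the null model under its fitted
covariance, the score is U = g' P y, its variance V = g' P g, the chi-square
statistic U^2/V, and the effect size and standard error are approximated as
beta = U/V and se = V^{-1/2}.  The percent of variance explained (PVE) is
approximated as (U^2/V)/(n - k).  On top of the per-variant tests sit the
QC filters (minor allele count, per-genotype depth), the per-chromosome
iterative conditional analysis that discovers independent sentinel variants,
the joint model that re-estimates all sentinels simultaneously, the joint
multi-parameter PVE, and Cochran's Q for cross-population effect
heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeBlock
from .lmm import TelomereLMMResults, TwoStageLMM

GENOME_WIDE_P = 5e-9


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Multiplicity-corrected per-test significance threshold."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def filter_variants(block: GenotypeBlock, mac_min: int = 5,
                    dp_threshold: float = 10, dp_frac: float = 0.10,
                    ) -> GenotypeBlock:
    """QC filter: pooled MAC >= mac_min and adequate sequencing depth.

    A variant is retained only if the fraction of samples with genotype
    depth below ``dp_threshold`` is strictly below ``dp_frac`` (a variant
    with exactly 10% low-depth samples is removed).
    """
    keep = block.mac() >= mac_min
    if block.dp is not None:
        low = np.mean(block.dp < dp_threshold, axis=0)
        keep &= low < dp_frac
    return block.subset_variants(keep)


def _imputed_genotypes(block: GenotypeBlock) -> np.ndarray:
    """Dosages with missing genotypes replaced by the variant mean."""
    g = block.dosages.copy()
    means = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    nan_r, nan_c = np.nonzero(np.isnan(g))
    g[nan_r, nan_c] = means[nan_c]
    return g


def score_tests(fit2: TelomereLMMResults, block: GenotypeBlock,
                ) -> pd.DataFrame:
    """Score tests of association for every variant in the block.

    Returns a table with score U, variance V, beta, se, p and PVE per
    variant.  Monomorphic variants (V = 0) are flagged with NaN statistics
    rather than failing.
    """
    if not fit2.converged:
        raise ValueError("null model fit did not converge")
    g = _imputed_genotypes(block)
    py = fit2.py
    pg = fit2.project(g)
    u = g.T @ py
    v = np.einsum("ij,ij->j", g, pg)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = v > np.finfo(float).eps * fit2.nobs
        chi2 = np.where(ok, u * u / v, np.nan)
        beta = np.where(ok, u / v, np.nan)
        se = np.where(ok, 1.0 / np.sqrt(v), np.nan)
        p = np.where(ok, stats.chi2.sf(chi2, df=1), np.nan)
    pve = pve_single(chi2, fit2.nobs, fit2.k_exog)
    out = block.variants.copy()
    out["mac"] = block.mac().astype(int)
    out["maf"] = block.maf()
    out["score_u"] = u
    out["score_var_v"] = v
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["pve"] = pve
    return out


def pve_single(chi2: np.ndarray | float, n: int, k: int) -> np.ndarray | float:
    """Percent of variance explained, approximated from the score test.

    PVE = (U^2/V) / (n - k); an approximation to the partial R^2 that is
    accurate for small per-variant effects.
    """
    if n <= k:
        raise ValueError(f"n={n} must exceed covariate count k={k}")
    return chi2 / (n - k)


def joint_pve(fit2: TelomereLMMResults, block: GenotypeBlock,
              variant_ids: list[str] | None = None) -> float:
    """Joint PVE of a variant set from a multi-parameter score test.

    PVE_joint = U' V^{-1} U / (n - k), with U the score vector and V the
    score covariance of the set under the null fit; accounting for the
    covariance avoids double counting shared signal among correlated
    variants.  Raises on a singular V (e.g. perfectly correlated variants).
    """
    sub = block
    if variant_ids is not None:
        idx = block.variants["id"].isin(variant_ids).to_numpy()
        sub = block.subset_variants(idx)
    g = _imputed_genotypes(sub)
    u = g.T @ fit2.py
    v = g.T @ fit2.project(g)
    cond = np.linalg.cond(v)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "score covariance V is singular; variant set contains "
            "perfectly correlated variants")
    stat = float(u @ np.linalg.solve(v, u))
    return min(stat / (fit2.nobs - fit2.k_exog), 1.0)


@dataclass(frozen=True)
class Sentinel:
    variant_id: str
    chrom: str
    pos: int
    round: int
    p: float
    beta: float


def iterative_conditional(two_stage: TwoStageLMM, block: GenotypeBlock,
                          threshold: float = GENOME_WIDE_P,
                          exclusions: tuple[str, ...] = (),
                          max_rounds: int = 25) -> list[Sentinel]:
    """Per-chromosome iterative conditional sentinel discovery.

    Round 0 tests all variants against the unconditional two-stage fit; the
    minimum-p variant below ``threshold`` (and not in ``exclusions``, a
    user-supplied quality-failure list) becomes a sentinel and enters the
    conditioning set, the two-stage model is refit with the conditioning
    genotypes as fixed effects, and testing repeats until no variant crosses
    the threshold.  Ties break on smaller p, then larger \\|beta\\|, then
    smaller genomic coordinate.
    """
    chroms = block.variants["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError(
            f"iterative_conditional operates per chromosome, got {list(chroms)}")
    sentinels: list[Sentinel] = []
    cond_ids: list[str] = []
    seen: set[frozenset] = set()
    g_all = _imputed_genotypes(block)
    ids = block.variants["id"].to_numpy()
    for rnd in range(max_rounds):
        key = frozenset(cond_ids)
        if key in seen:
            raise RuntimeError(
                f"conditioning set revisited (oscillation): {sorted(key)}")
        seen.add(key)
        extra = None
        if cond_ids:
            extra = g_all[:, np.isin(ids, cond_ids)]
        _, fit2 = two_stage.fit(extra_fixed=extra, extra_names=list(cond_ids))
        testable = ~np.isin(ids, cond_ids + list(exclusions))
        res = score_tests(fit2, block.subset_variants(testable))
        res = res.dropna(subset=["p"])
        hits = res[res["p"] < threshold]
        if hits.empty:
            break
        best = hits.sort_values(
            ["p", "beta", "pos"], key=lambda s: -s.abs() if s.name == "beta" else s,
        ).iloc[0]
        sentinels.append(Sentinel(
            variant_id=str(best["id"]), chrom=str(best["chrom"]),
            pos=int(best["pos"]), round=rnd, p=float(best["p"]),
            beta=float(best["beta"])))
        cond_ids.append(str(best["id"]))
    return sentinels


def joint_model(two_stage: TwoStageLMM, block: GenotypeBlock,
                sentinel_ids: list[str]) -> pd.DataFrame:
    """Joint fixed-effect estimates for a set of sentinel variants.

    Stage 1 is the primary (unconditional) fit; Stage 2 adds all sentinel
    genotypes simultaneously as additive fixed effects, so the estimates are
    mutually adjusted.  Collinear sentinels raise an error naming the
    offending pair.
    """
    idx = block.variants["id"].isin(sentinel_ids).to_numpy()
    sub = block.subset_variants(idx)
    order = {v: i for i, v in enumerate(sub.variants["id"])}
    g = _imputed_genotypes(sub)
    corr = np.corrcoef(g.T) if g.shape[1] > 1 else np.ones((1, 1))
    iu = np.triu_indices(g.shape[1], k=1)
    bad = np.flatnonzero(np.abs(corr[iu]) > 1.0 - 1e-10)
    if bad.size:
        i, j = iu[0][bad[0]], iu[1][bad[0]]
        ids = list(sub.variants["id"])
        raise ValueError(f"collinear sentinels: {ids[i]} and {ids[j]}")
    names = list(sub.variants["id"].astype(str))
    _, fit2 = two_stage.fit(stage2_fixed=g, stage2_names=names)
    est = fit2.fe_params[names]
    se = fit2.bse[names]
    z = est / se
    return pd.DataFrame({
        "id": names,
        "beta": est.to_numpy(),
        "se": se.to_numpy(),
        "p": 2.0 * stats.norm.sf(np.abs(z.to_numpy())),
    }).sort_values("id", key=lambda s: s.map(order)).reset_index(drop=True)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity test across strata."""

    q_stat: float
    df: int
    p: float


def cochran_q(betas, ses) -> HeterogeneityResult | None:
    """Cochran's Q for effect-size heterogeneity across population strata.

    Inverse-variance weights w = 1/se^2, Q = sum w (beta - weighted mean)^2,
    p from the upper tail of chi-square with (strata - 1) degrees of
    freedom.  Strata with missing estimates are dropped; fewer than two
    usable strata yields None (missing result).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ok = np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
    betas, ses = betas[ok], ses[ok]
    if betas.size < 2:
        return None
    w = 1.0 / ses ** 2
    mean = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - mean) ** 2))
    df = betas.size - 1
    return HeterogeneityResult(q_stat=q, df=df,
                               p=float(stats.chi2.sf(q, df)))
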