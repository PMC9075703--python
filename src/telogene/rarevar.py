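"""Deleterious rare-variant aggregation and SMMAT-style gene-based tests.

Per gene, rare coding variants (pooled MAF < 1%, singletons included) are
collected if their consequence is loss-of-function-like (stop gain/loss,
start loss, transcript ablation/amplification, splice acceptor/donor,
frameshift) or if they are missense and predicted damaging by at least one
of REVEL > 0.5, M-CAP "Damaging", or CADD PHRED > 30.  Genes with a
cumulative minor allele count below 5 are dropped.  Variants are weighted by
the Beta(1, 25) density at their MAF (25 (1-MAF)^24), up-weighting the
rarest variants.

The gene test is the SMMAT hybrid: a burden score test on the weighted
genotype sum, plus a SKAT-type quadratic-form test on the variant scores
orthogonalized to the burden direction (tail probability by Davies'
integration with a Liu moment-matching fallback).  The two components are
asymptotically independent under the null and are combined with Fisher's
method (chi-square with 4 df).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import _imputed_genotypes
from .data import GenotypeBlock
from .lmm import TelomereLMMResults, TwoStageLMM
from .qfc import quad_form_pvalue

LOF_CONSEQUENCES = {
    "stop_gain", "stop_loss", "start_loss", "transcript_ablation",
    "transcript_amplification", "splice_acceptor", "splice_donor",
    "frameshift",
}
OTHER_CONSEQUENCES = {
    "missense", "synonymous", "intron", "intergenic", "utr3", "utr5",
    "upstream", "downstream", "ncrna", "non_frameshift_insertion",
    "non_frameshift_deletion", "non_frameshift_substitution", "unknown",
}


def _normalize_consequence(c: str) -> str:
    c = str(c).strip().lower().replace("-", "_").replace(" ", "_")
    for suffix in ("_variant", "_insertion", "_deletion", "_substitution"):
        if c.endswith(suffix) and c.removesuffix(suffix) in LOF_CONSEQUENCES:
            return c.removesuffix(suffix)
    if c.startswith("stop") and c in {"stopgain", "stoploss"}:
        return "stop_" + c[4:]
    return c


@dataclass
class VariantSet:
    """Qualifying rare variants of one gene, with weights."""

    gene: str
    variant_ids: list[str]
    maf: np.ndarray
    weights: np.ndarray
    rule_tags: list[str] = field(default_factory=list)

    @property
    def cumulative_mac(self) -> int:
        return int(self._cum_mac)

    _cum_mac: int = 0

    def drop(self, variant_ids: set[str]) -> "VariantSet":
        keep = [i for i, v in enumerate(self.variant_ids)
                if v not in variant_ids]
        vs = VariantSet(
            gene=self.gene,
            variant_ids=[self.variant_ids[i] for i in keep],
            maf=self.maf[keep], weights=self.weights[keep],
            rule_tags=[self.rule_tags[i] for i in keep] if self.rule_tags else [])
        vs._cum_mac = self._cum_mac
        return vs


def maf_weights(mafs: np.ndarray, a: float = 1.0, b: float = 25.0,
                ) -> np.ndarray:
    """Beta(a, b) density evaluated at the MAF (default Beta(1, 25))."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs >= 1)):
        raise ValueError("MAFs must lie strictly inside (0, 1)")
    return stats.beta.pdf(mafs, a, b)


def qualifying_mask(annotations: pd.DataFrame) -> np.ndarray:
    """Boolean deleteriousness mask over an annotation table.

    Expects columns consequence, revel, mcap, cadd (scores may be missing;
    a variant with missing scores qualifies only via its consequence class).
    Unknown consequence strings raise a validation error listing them.
    """
    cons = annotations["consequence"].map(_normalize_consequence)
    unknown = sorted(set(cons) - LOF_CONSEQUENCES - OTHER_CONSEQUENCES)
    if unknown:
        raise ValueError(f"unknown consequence strings: {unknown}")
    lof = cons.isin(LOF_CONSEQUENCES)
    revel = pd.to_numeric(annotations.get("revel"), errors="coerce")
    cadd = pd.to_numeric(annotations.get("cadd"), errors="coerce")
    mcap = annotations.get("mcap")
    damaging_mcap = (mcap.astype(str).str.strip().str.lower() == "damaging"
                     if mcap is not None else pd.Series(False, index=cons.index))
    missense_hit = (cons == "missense") & (
        (revel > 0.5).fillna(False)
        | damaging_mcap
        | (cadd > 30).fillna(False))
    return (lof | missense_hit).to_numpy()


def build_variant_sets(annotations: pd.DataFrame, block: GenotypeBlock,
                       maf_max: float = 0.01, cum_mac_min: int = 5,
                       ) -> dict[str, VariantSet]:
    """Per-gene qualifying variant sets with Beta(1,25) weights.

    ``annotations`` needs columns variant_id, gene, consequence, revel,
    mcap, cadd.  Pooled MAF and MAC come from the genotype block.  Genes
    whose retained variants sum to a cumulative MAC below ``cum_mac_min``
    are dropped.
    """
    qual = qualifying_mask(annotations)
    maf = pd.Series(block.maf(), index=block.variants["id"].to_numpy())
    mac = pd.Series(block.mac(), index=block.variants["id"].to_numpy())
    cons = annotations["consequence"].map(_normalize_consequence)
    sets: dict[str, VariantSet] = {}
    for gene, sub in annotations[qual].groupby("gene"):
        vids = [v for v in sub["variant_id"]
                if v in maf.index and 0 < maf[v] < maf_max]
        if not vids:
            continue
        cum = int(mac[vids].sum())
        if cum < cum_mac_min:
            continue
        m = maf[vids].to_numpy()
        vs = VariantSet(gene=str(gene), variant_ids=vids, maf=m,
                        weights=maf_weights(m),
                        rule_tags=list(cons.loc[sub.index[
                            sub["variant_id"].isin(vids)]]))
        vs._cum_mac = cum
        sets[str(gene)] = vs
    return sets


@dataclass(frozen=True)
class SMMATResult:
    gene: str
    n_variants: int
    cumulative_mac: int
    p_burden: float
    p_skat_adjusted: float
    p_combined: float
    skat_method: str = "davies"


def fisher_combination(p1: float, p2: float) -> float:
    """Fisher's method for two independent p-values (chi-square, 4 df)."""
    stat = -2.0 * (np.log(p1) + np.log(p2))
    return float(stats.chi2.sf(stat, df=4))


def smmat_test(fit2: TelomereLMMResults, vset: VariantSet,
               block: GenotypeBlock) -> SMMATResult | None:
    """SMMAT hybrid gene-based test against a Stage-2 null fit.

    Computes the weighted burden score test and the burden-adjusted
    SKAT-type quadratic form; combines them with Fisher's method.  For a
    single-variant set the burden test is the single-variant score test and
    there is no SKAT component.  Returns None for an empty set.
    """
    if not vset.variant_ids:
        return None
    idx = block.variants["id"].isin(vset.variant_ids).to_numpy()
    sub = block.subset_variants(idx)
    # align weights to the block's column order
    pos = [vset.variant_ids.index(v) for v in sub.variants["id"]]
    w = vset.weights[pos]
    g = _imputed_genotypes(sub)
    py = fit2.py
    s = w * (g.T @ py)
    phi = np.outer(w, w) * (g.T @ fit2.project(g))
    t_burden = float(s.sum())
    lam_b = float(phi.sum())
    if lam_b <= 0:
        return None
    p_burden = float(stats.chi2.sf(t_burden ** 2 / lam_b, df=1))
    m = len(s)
    if m == 1:
        return SMMATResult(vset.gene, 1, vset.cumulative_mac,
                           p_burden, np.nan, p_burden, "none")
    phi1 = phi.sum(axis=1)
    s_adj = s - phi1 * (t_burden / lam_b)
    q_adj = float(s_adj @ s_adj)
    cov_adj = phi - np.outer(phi1, phi1) / lam_b
    lam = np.linalg.eigvalsh(cov_adj)
    lam = lam[lam > 1e-10 * max(lam.max(), 1e-300)]
    if lam.size == 0:
        return SMMATResult(vset.gene, m, vset.cumulative_mac,
                           p_burden, np.nan, p_burden, "none")
    p_skat, method = quad_form_pvalue(q_adj, lam)
    p_skat = min(max(p_skat, 1e-300), 1.0)
    return SMMATResult(vset.gene, m, vset.cumulative_mac, p_burden,
                       p_skat, fisher_combination(p_burden, p_skat), method)


def leave_one_out(fit2: TelomereLMMResults, vset: VariantSet,
                  block: GenotypeBlock) -> pd.DataFrame | None:
    """Re-test the gene dropping one variant at a time.

    A variant whose removal sharply weakens the signal is a driver; a gene
    whose signal persists under every drop is supported by cumulative
    evidence across variants.  Returns None for sets of size < 2.
    """
    if len(vset.variant_ids) < 2:
        return None
    rows = []
    for vid in vset.variant_ids:
        res = smmat_test(fit2, vset.drop({vid}), block)
        rows.append({"dropped": vid,
                     "p_burden": res.p_burden,
                     "p_skat": res.p_skat_adjusted,
                     "p_combined": res.p_combined})
    return pd.DataFrame(rows)


def conditional_gene_test(two_stage: TwoStageLMM, vset: VariantSet,
                          block: GenotypeBlock,
                          sentinel_ids: list[str],
                          ) -> SMMATResult | None:
    """Gene test conditional on genome-wide significant sentinel variants.

    Sentinels enter both stages of the null model as fixed-effect
    covariates and are excised from the variant set before testing; a set
    that empties after excision yields None.
    """
    vset2 = vset.drop(set(sentinel_ids))
    if not vset2.variant_ids:
        return None
    if sentinel_ids:
        idx = block.variants["id"].isin(sentinel_ids).to_numpy()
        g = _imputed_genotypes(block.subset_variants(idx))
        _, fit2 = two_stage.fit(extra_fixed=g,
                                extra_names=[f"sent_{i}" for i in
                                             range(g.shape[1])])
    else:
        _, fit2 = two_stage.fit()
    return smmat_test(fit2, vset2, block)


def gene_test_table(results: list[SMMATResult]) -> pd.DataFrame:
    rows = [{"gene": r.gene, "n_variants": r.n_variants,
             "cum_mac": r.cumulative_mac, "p_burden": r.p_burden,
             "p_skat": r.p_skat_adjusted, "p_combined": r.p_combined,
             "flag": r.skat_method} for r in results if r is not None]
    return pd.DataFrame(rows)
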