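"""Variant QC filters, score tests, conditional/joint analysis, Cochran's Q."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telogene import synthio
from telogene.assoc import (
    bonferroni_threshold,
    cochran_q,
    filter_variants,
    iterative_conditional,
    joint_model,
    joint_pve,
    pve_single,
    score_tests,
)
from telogene.data import GenotypeBlock
from telogene.lmm import TwoStageLMM, fit_null_model


def _toy_block(dosages, dp=None, ids=None):
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(1, m + 1) * 100,
        "id": ids or [f"v{j + 1}" for j in range(m)],
        "ref": "A", "alt": "G"})
    return GenotypeBlock(samples=[f"s{i}" for i in range(n)],
                         variants=variants, dosages=dosages,
                         dp=None if dp is None else np.asarray(dp, float))


# ----------------------------------------------------------------- filters


def test_filter_mac_rule():
    # 20 samples; variant 1 has MAC 4, variant 2 has MAC 5
    d = np.zeros((20, 2))
    d[:4, 0] = 1
    d[:5, 1] = 1
    out = filter_variants(_toy_block(d), mac_min=5)
    assert list(out.variants["id"]) == ["v2"]


def test_filter_dp_boundary_strict():
    # exactly 10% of samples at DP 9 -> removed (strict inequality)
    d = np.tile([[1.0, 1.0]], (20, 1))
    dp = np.full((20, 2), 30.0)
    dp[:2, 0] = 9.0   # 10% low depth -> removed
    dp[:1, 1] = 9.0   # 5% low depth -> kept
    out = filter_variants(_toy_block(d, dp))
    assert list(out.variants["id"]) == ["v2"]


def test_filter_matches_hand_enumeration():
    """Six planted variants: survivors equal the hand-worked set."""
    n = 40
    d = np.zeros((n, 6))
    d[:10, 0] = 1          # MAC 10, clean          -> keep
    d[:2, 1] = 1           # MAC 2                  -> drop (MAC)
    d[:10, 2] = 1          # MAC 10, 15% low DP     -> drop (DP)
    d[:, 3] = 2.0          # all hom-alt: MAC 0     -> drop (minor side)
    d[:20, 4] = 1          # MAC 20, 7.5% low DP    -> keep
    d[:3, 5] = 2           # MAC 6, clean           -> keep
    dp = np.full((n, 6), 30.0)
    dp[:6, 2] = 5.0
    dp[:3, 4] = 5.0
    out = filter_variants(_toy_block(d, dp))
    assert list(out.variants["id"]) == ["v1", "v5", "v6"]


# -------------------------------------------------------------- score tests


def test_score_test_matches_dense_matrix_oracle(unrelated_cohort):
    """Identity kinship, one stratum: p equals a dense-matrix score test.

    The oracle rebuilds P = S^-1 - S^-1 X (X'S^-1X)^-1 X'S^-1 as an explicit
    dense matrix at the fitted variance components and recomputes U, V, p
    from scratch; it also agrees closely with the plain OLS-residual score
    test because the GLS fit collapses to OLS here.
    """
    _, cohort, block, kinship = unrelated_cohort
    fit = fit_null_model(cohort, "tl", ["age", "sex"], kinship, "group")
    res = score_tests(fit, block)
    n = len(cohort)
    x = np.column_stack([np.ones(n), cohort["age"], cohort["sex"]])
    y = cohort["tl"].to_numpy()
    sigma = (fit.var_genetic + fit.var_residual_by_group.iloc[0]) * np.eye(n)
    si = np.linalg.inv(sigma)
    p_mat = si - si @ x @ np.linalg.solve(x.T @ si @ x, x.T @ si)
    h = x @ np.linalg.solve(x.T @ x, x.T)
    r = y - h @ y
    s2 = r @ r / (n - x.shape[1])
    for j in range(block.n_variants):
        g = block.dosages[:, j]
        u = g @ p_mat @ y
        v = g @ p_mat @ g
        p_oracle = stats.chi2.sf(u * u / v, 1)
        assert res["p"].iloc[j] == pytest.approx(p_oracle, abs=1e-8)
        # and the plain OLS score test, up to REML-vs-OLS variance wobble
        g_res = g - h @ g
        chi2_ols = (g_res @ r) ** 2 / (g_res @ g_res * s2)
        assert res["p"].iloc[j] == pytest.approx(
            stats.chi2.sf(chi2_ols, 1), rel=0.05, abs=1e-12)


def test_score_test_covariate_copy_annihilated(unrelated_cohort):
    """A variant identical to a covariate is annihilated by the projection."""
    _, cohort, _, kinship = unrelated_cohort
    fit = fit_null_model(cohort, "tl", ["age", "sex"], kinship, "group")
    g = cohort["sex"].to_numpy()
    blk = _toy_block(g[:, None])
    res = score_tests(fit, blk)
    scale = float(np.abs(fit.py).sum())
    assert abs(res["score_u"].iloc[0]) < 1e-8 * scale
    # V collapses to zero as well: the test is flagged missing, not fatal
    assert np.isnan(res["p"].iloc[0]) or res["p"].iloc[0] > 0.99


def test_score_test_monomorphic_flagged(fitted_two_stage):
    _, _, fit2 = fitted_two_stage
    blk = _toy_block(np.zeros((fit2.nobs, 1)))
    res = score_tests(fit2, blk)
    assert np.isnan(res["p"].iloc[0])


def test_score_test_beta_se_identities(fitted_two_stage, family_cohort):
    _, _, block, _ = family_cohort
    _, _, fit2 = fitted_two_stage
    res = score_tests(fit2, block)
    np.testing.assert_allclose(res["beta"], res["score_u"] / res["score_var_v"])
    np.testing.assert_allclose(res["se"], res["score_var_v"] ** -0.5)


# -------------------------------------------------------------------- pve


def test_pve_trivial_and_validation():
    assert pve_single(0.0, 100, 3) == 0.0
    assert pve_single(5.0, 103, 3) == pve_single(5.0, 103, 3)
    with pytest.raises(ValueError):
        pve_single(1.0, 3, 3)


def test_pve_matches_ols_partial_r2():
    """At n=5000 unrelated samples, PVE tracks the OLS partial R^2."""
    spec = synthio.CohortSimSpec(
        n_families=5000, family_size=1, n_strata=1,
        stratum_residual_sd=(450.0,), h2=0.0,
        causal_variants=((0.3, -40.0),), seed=44)
    cohort, block, kinship = synthio.simulate_cohort(spec)
    fit = fit_null_model(cohort, "tl", ["age", "sex"], kinship, "group")
    res = score_tests(fit, block)
    x = np.column_stack([np.ones(len(cohort)), cohort["age"], cohort["sex"]])
    y = cohort["tl"].to_numpy()
    g = block.dosages[:, 0]
    rss0 = np.sum((y - x @ np.linalg.lstsq(x, y, rcond=None)[0]) ** 2)
    xg = np.column_stack([x, g])
    rss1 = np.sum((y - xg @ np.linalg.lstsq(xg, y, rcond=None)[0]) ** 2)
    partial_r2 = (rss0 - rss1) / rss0
    assert res["pve"].iloc[0] == pytest.approx(partial_r2, rel=0.20)


def test_joint_pve_reductions(fitted_two_stage, family_cohort):
    _, _, block, _ = family_cohort
    _, _, fit2 = fitted_two_stage
    res = score_tests(fit2, block)
    single = joint_pve(fit2, block, ["var1"])
    assert single == pytest.approx(res["pve"].iloc[0], rel=1e-9)
    # duplicated variant -> singular score covariance
    dup = block.subset_variants([0, 0])
    with pytest.raises(np.linalg.LinAlgError):
        joint_pve(fit2, dup)


def test_joint_pve_independent_variants_additive():
    spec = synthio.CohortSimSpec(
        n_families=1000, family_size=1, n_strata=1,
        stratum_residual_sd=(400.0,), h2=0.0,
        causal_variants=((0.3, -50.0), (0.2, 60.0)), seed=45)
    cohort, block, kinship = synthio.simulate_cohort(spec)
    fit = fit_null_model(cohort, "tl", ["age", "sex"], kinship, "group")
    res = score_tests(fit, block)
    joint = joint_pve(fit, block, ["var1", "var2"])
    assert joint == pytest.approx(res["pve"].sum(), rel=0.10)


# -------------------------------------------------------------- conditional


def test_iterative_conditional_empty_when_no_signal(family_cohort):
    _, cohort, block, kinship = family_cohort
    ts = TwoStageLMM(cohort, "tl", ["age", "sex"], kinship, "group")
    sentinels = iterative_conditional(ts, block, threshold=5e-9)
    assert sentinels == []


def _strong_cohort(seed, betas=((0.3, -180.0), (0.25, 170.0))):
    spec = synthio.CohortSimSpec(
        n_families=500, family_size=4, h2=0.4,
        causal_variants=tuple(betas), n_null_variants=30, seed=seed)
    return synthio.simulate_cohort(spec)


def test_iterative_conditional_two_unlinked_causals():
    cohort, block, kinship = _strong_cohort(46)
    ts = TwoStageLMM(cohort, "tl", ["age", "sex"], kinship, "group")
    sentinels = iterative_conditional(ts, block, threshold=5e-9)
    assert sorted(s.variant_id for s in sentinels) == ["var1", "var2"]
    assert [s.round for s in sorted(sentinels, key=lambda s: s.round)] == [0, 1]


def test_iterative_conditional_respects_exclusions():
    cohort, block, kinship = _strong_cohort(46, betas=((0.3, -180.0),))
    ts = TwoStageLMM(cohort, "tl", ["age", "sex"], kinship, "group")
    sentinels = iterative_conditional(ts, block, threshold=5e-9,
                                      exclusions=("var1",))
    assert "var1" not in {s.variant_id for s in sentinels}


def test_iterative_conditional_proxy_resolution():
    """One causal + near-perfect proxies: a single sentinel, high r2."""
    cohort, block, kinship = _strong_cohort(47, betas=((0.3, -180.0),))
    rng = np.random.default_rng(5)
    g = block.dosages[:, 0]
    # proxy: same genotypes with 1% random flips
    proxy = g.copy()
    flip = rng.random(g.size) < 0.01
    proxy[flip] = rng.integers(0, 3, flip.sum())
    dos = np.column_stack([block.dosages, proxy])
    var = pd.concat([block.variants, pd.DataFrame([{
        "chrom": "chr1", "pos": 999_000, "id": "proxy1",
        "ref": "A", "alt": "G"}])], ignore_index=True)
    block2 = GenotypeBlock(samples=block.samples, variants=var, dosages=dos)
    ts = TwoStageLMM(cohort, "tl", ["age", "sex"], kinship, "group")
    sentinels = iterative_conditional(ts, block2, threshold=5e-9)
    assert len(sentinels) == 1
    r2 = np.corrcoef(block2.dosages[:, block2.variants["id"].tolist().index(
        sentinels[0].variant_id)], g)[0, 1] ** 2
    assert r2 > 0.9


# ------------------------------------------------------------------- joint


def test_joint_single_sentinel_equals_stage2_fixed(family_cohort):
    cohort, block, kinship = _strong_cohort(48, betas=((0.3, -180.0),))
    ts = TwoStageLMM(cohort, "tl", ["age", "sex"], kinship, "group")
    res = joint_model(ts, block, ["var1"])
    _, fit2 = ts.fit(stage2_fixed=block.dosages[:, [0]],
                     stage2_names=["var1"])
    assert res["beta"].iloc[0] == pytest.approx(fit2.fe_params["var1"])
    assert res["se"].iloc[0] == pytest.approx(fit2.bse["var1"])


def test_joint_independent_close_to_marginal():
    cohort, block, kinship = _strong_cohort(49)
    ts = TwoStageLMM(cohort, "tl", ["age", "sex"], kinship, "group")
    _, fit2 = ts.fit()
    marg = score_tests(fit2, block).set_index("id")
    joint = joint_model(ts, block, ["var1", "var2"]).set_index("id")
    for vid in ["var1", "var2"]:
        assert joint.loc[vid, "beta"] == pytest.approx(
            marg.loc[vid, "beta"], rel=0.10)


def test_joint_collinear_sentinels_error():
    cohort, block, kinship = _strong_cohort(50, betas=((0.3, -180.0),))
    dup = GenotypeBlock(
        samples=block.samples,
        variants=pd.concat([block.variants, block.variants.iloc[[0]].assign(
            id="var1_dup", pos=999)], ignore_index=True),
        dosages=np.column_stack([block.dosages, block.dosages[:, 0]]))
    ts = TwoStageLMM(cohort, "tl", ["age", "sex"], kinship, "group")
    with pytest.raises(ValueError, match="collinear"):
        joint_model(ts, dup, ["var1", "var1_dup"])


# --------------------------------------------------------------- cochran q


def test_cochran_q_all_equal():
    res = cochran_q([2.0, 2.0, 2.0], [1.0, 0.5, 2.0])
    assert res.q_stat == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_cochran_q_closed_form():
    res = cochran_q([1.0, -1.0], [1.0, 1.0])
    assert res.q_stat == pytest.approx(2.0)
    assert res.df == 1
    assert res.p == pytest.approx(0.1573, abs=2e-4)


def test_cochran_q_location_invariance():
    a = cochran_q([1.0, 3.0, -2.0], [0.5, 1.0, 2.0])
    b = cochran_q([11.0, 13.0, 8.0], [0.5, 1.0, 2.0])
    assert a.q_stat == pytest.approx(b.q_stat)


def test_cochran_q_missing_strata():
    assert cochran_q([1.0, np.nan], [1.0, 1.0]) is None
    assert cochran_q([1.0], [1.0]) is None


# --------------------------------------------------------------- thresholds


def test_bonferroni_threshold():
    assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)
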