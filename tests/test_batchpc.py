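"""Coverage binning, bin filters, randomized SVD and TL residualization."""

import numpy as np
import pandas as pd
import pytest

from telogene import batchpc, synthio
from telogene.batchpc import (
    BinDepthMatrix,
    bin_depths,
    component_diagnostics,
    filter_bins,
    fit_batch_pcs,
    group_r2,
    normalize_bins,
    randomized_svd,
    residualize_tl,
)
from telogene.telseq import DegenerateInputError


def _bins(n, bin_size=1000, chrom="chr1"):
    starts = np.arange(n) * bin_size
    return pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + bin_size,
        "mappability": 1.0, "blacklist": False,
    })


# --------------------------------------------------------------- bin_depths


def test_bin_depth_single_read():
    m = bin_depths({"s1": [("chr1", 100, 100)]}, _bins(2))
    assert m.depths[0, 0] == pytest.approx(0.1)
    assert m.depths[0, 1] == 0.0


def test_bin_depth_straddling_read():
    m = bin_depths({"s1": [("chr1", 940, 100)]}, _bins(2))
    assert m.depths[0, 0] == pytest.approx(0.06)
    assert m.depths[0, 1] == pytest.approx(0.04)


def test_bin_depth_empty_sample():
    m = bin_depths({"s1": []}, _bins(3))
    assert np.all(m.depths == 0)


def test_bin_depth_matches_pileup_oracle(rng):
    """Bin means equal a per-base pileup computed independently."""
    n_bins, bin_size = 20, 1000
    reads = [("chr1", int(rng.integers(0, n_bins * bin_size - 200)),
              int(rng.integers(50, 200))) for _ in range(300)]
    m = bin_depths({"s1": reads}, _bins(n_bins))
    pile = np.zeros(n_bins * bin_size)
    for _, start, length in reads:
        pile[start:start + length] += 1
    oracle = pile.reshape(n_bins, bin_size).mean(axis=1)
    np.testing.assert_allclose(m.depths[0], oracle, atol=1e-12)


# -------------------------------------------------------------- filter_bins


def test_filter_bins_toy_rules():
    bins = _bins(5)
    bins.loc[0, "mappability"] = 0.9
    bins.loc[1, "blacklist"] = True
    bins.loc[2, "chrom"] = "chrX"
    m = BinDepthMatrix(samples=["s1"], bins=bins, depths=np.ones((1, 5)))
    kept = filter_bins(m)
    assert kept.n_bins == 2
    assert list(kept.bins["start"]) == [3000, 4000]


def test_filter_bins_identity_when_clean():
    m = BinDepthMatrix(samples=["s1"], bins=_bins(4),
                       depths=np.arange(4.0)[None, :])
    np.testing.assert_array_equal(filter_bins(m).depths, m.depths)


def test_filter_bins_all_removed_errors():
    bins = _bins(3, chrom="chrX")
    m = BinDepthMatrix(samples=["s1"], bins=bins, depths=np.ones((1, 3)))
    with pytest.raises(DegenerateInputError):
        filter_bins(m)


# ------------------------------------------------------------ normalize_bins


def test_normalize_constant_sample_and_centering(rng):
    depths = rng.uniform(10, 60, size=(8, 30))
    depths[0] = 7.0  # constant-depth sample
    m = BinDepthMatrix(samples=[f"s{i}" for i in range(8)], bins=_bins(30),
                       depths=depths)
    x = normalize_bins(m)
    # constant sample row is 1.0 before centering
    np.testing.assert_allclose(x[0] + (depths / depths.mean(1, keepdims=True)
                                       ).mean(0), 1.0, atol=1e-12)
    assert np.abs(x.mean(axis=0)).max() < 1e-12


def test_normalize_scale_invariance(rng):
    depths = rng.uniform(10, 60, size=(5, 20))
    m1 = BinDepthMatrix(samples=list("abcde"), bins=_bins(20), depths=depths)
    depths2 = depths.copy()
    depths2[2] *= 2.0
    m2 = BinDepthMatrix(samples=list("abcde"), bins=_bins(20), depths=depths2)
    np.testing.assert_allclose(normalize_bins(m1), normalize_bins(m2),
                               atol=1e-12)


def test_normalize_zero_mean_sample_errors():
    depths = np.ones((2, 4))
    depths[1] = 0.0
    m = BinDepthMatrix(samples=["good", "empty"], bins=_bins(4),
                       depths=depths)
    with pytest.raises(ValueError, match="empty"):
        normalize_bins(m)


# ------------------------------------------------------------ randomized_svd


def test_rsvd_rank_one_closed_form(rng):
    u = rng.standard_normal(30)
    v = rng.standard_normal(50)
    x = np.outer(u, v)
    pcs = randomized_svd(x, 2, seed=0)
    assert pcs.singular_values[0] == pytest.approx(
        np.linalg.norm(u) * np.linalg.norm(v), abs=1e-8)
    assert pcs.singular_values[1] <= 1e-8


def test_rsvd_matches_exact_svd(rng):
    """Sketch covering the minor dimension reproduces the exact SVD."""
    x = rng.standard_normal((60, 40))
    pcs = randomized_svd(x, 10, oversampling=30, seed=3)
    exact = np.linalg.svd(x, compute_uv=False)[:10]
    np.testing.assert_allclose(pcs.singular_values, exact, rtol=1e-6)


def test_rsvd_matches_sklearn_oracle(rng):
    """Agreement with scikit-learn's randomized SVD on a low-rank matrix."""
    sklearn = pytest.importorskip("sklearn.utils.extmath")
    base = rng.standard_normal((50, 5)) @ rng.standard_normal((5, 30))
    x = base + 1e-9 * rng.standard_normal((50, 30))
    pcs = randomized_svd(x, 5, seed=7)
    _, s, _ = sklearn.randomized_svd(x, n_components=5, n_iter=4,
                                     random_state=0)
    np.testing.assert_allclose(pcs.singular_values, s, rtol=1e-6)


def test_rsvd_deterministic(rng):
    x = rng.standard_normal((25, 40))
    a = randomized_svd(x, 4, seed=11)
    b = randomized_svd(x, 4, seed=11)
    np.testing.assert_array_equal(a.scores, b.scores)
    np.testing.assert_array_equal(a.singular_values, b.singular_values)


def test_rsvd_dimension_validation(rng):
    with pytest.raises(ValueError):
        randomized_svd(rng.standard_normal((5, 8)), 6)


def test_rsvd_scores_orthogonal(rng):
    x = rng.standard_normal((40, 60))
    x -= x.mean(axis=0)
    pcs = randomized_svd(x, 5, seed=2)
    gram = pcs.scores.T @ pcs.scores
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()


# ------------------------------------------------------------ residualize_tl


def test_residualize_zero_components_identity(rng):
    m, _ = synthio.simulate_coverage(30, 200, 2, seed=5)
    pcs = fit_batch_pcs(m, 2, seed=1)
    tl = rng.normal(3500, 400, 30)
    np.testing.assert_array_equal(residualize_tl(tl, pcs, 0), tl)


def test_residualize_orthogonal_and_mean_preserving(rng):
    m, _ = synthio.simulate_coverage(50, 300, 3, seed=6)
    pcs = fit_batch_pcs(m, 3, seed=2)
    tl = rng.normal(3500, 400, 50)
    adj = residualize_tl(tl, pcs, 3)
    for j in range(3):
        assert abs(np.corrcoef(adj - adj.mean(), pcs.scores[:, j])[0, 1]) < 1e-10
    assert adj.mean() == pytest.approx(tl.mean(), abs=1e-9)


def test_residualize_sample_mismatch_errors(rng):
    m, _ = synthio.simulate_coverage(20, 100, 2, seed=7)
    pcs = fit_batch_pcs(m, 2, seed=3)
    with pytest.raises(ValueError):
        residualize_tl(rng.normal(size=19), pcs)


def test_batch_correction_improves_tl(rng):
    """Planted factors contaminating coverage and TL are removed."""
    m, factors = synthio.simulate_coverage(100, 1000, 3, loading_scale=3.0,
                                           noise_sd=0.3, seed=8)
    tl_true = rng.normal(3500, 400, 100)
    tl_obs = synthio.contaminate_tl(tl_true, factors,
                                    np.array([300.0, -250.0, 200.0]))
    pcs = fit_batch_pcs(m, 3, seed=4)
    adj = residualize_tl(tl_obs, pcs, 3)
    assert abs(np.corrcoef(adj, tl_true)[0, 1]) > abs(
        np.corrcoef(tl_obs, tl_true)[0, 1])


def test_pipeline_recovers_planted_subspace():
    """filter -> normalize -> rSVD: principal angles < 5 degrees."""
    m, factors = synthio.simulate_coverage(80, 1500, 3, loading_scale=3.0,
                                           noise_sd=0.05, seed=9)
    pcs = fit_batch_pcs(m, 3, seed=5)
    qa, _ = np.linalg.qr(pcs.scores)
    qb, _ = np.linalg.qr(factors - factors.mean(axis=0))
    canon = np.clip(np.linalg.svd(qa.T @ qb, compute_uv=False), -1, 1)
    assert np.degrees(np.arccos(canon.min())) < 5.0


def test_ordering_invariance_low_rank():
    """Permuting bins and samples permutes the adjusted TL accordingly."""
    m, factors = synthio.simulate_coverage(40, 300, 3, noise_sd=0.0, seed=10,
                                           frac_blacklist=0, frac_lowmap=0,
                                           frac_chrx=0)
    tl = synthio.contaminate_tl(np.full(40, 3500.0), factors,
                                np.array([200.0, -100.0, 50.0]))
    rng = np.random.default_rng(1)
    bperm = rng.permutation(300)
    sperm = rng.permutation(40)
    m2 = BinDepthMatrix(samples=[m.samples[i] for i in sperm],
                        bins=m.bins.iloc[bperm], depths=m.depths[sperm][:, bperm])
    adj1 = residualize_tl(tl, fit_batch_pcs(m, 3, seed=6), 3)
    adj2 = residualize_tl(tl[sperm], fit_batch_pcs(m2, 3, seed=6), 3)
    np.testing.assert_allclose(adj2, adj1[sperm], atol=1e-6)


# ------------------------------------------------------------- diagnostics


def test_diagnostics_reference_is_tl(rng):
    m, _ = synthio.simulate_coverage(30, 200, 2, seed=11)
    pcs = fit_batch_pcs(m, 2, seed=7)
    tl = rng.normal(3500, 400, 30)
    table = component_diagnostics(tl, pcs, references={"tl": tl},
                                  grid=[0, 2])
    row0 = table[table["n_components"] == 0].iloc[0]
    assert row0["corr_tl"] == pytest.approx(1.0)


def test_diagnostics_single_group_r2_zero():
    vals = np.array([1.0, 2.0, 3.0])
    assert group_r2(vals, np.array(["a", "a", "a"])) == pytest.approx(0.0)


def test_diagnostics_requires_reference(rng):
    m, _ = synthio.simulate_coverage(10, 50, 1, seed=12)
    pcs = fit_batch_pcs(m, 1, seed=8)
    with pytest.raises(ValueError):
        component_diagnostics(rng.normal(size=10), pcs)


def test_between_batch_r2_nonincreasing():
    """Batch-label R^2 in adjusted TL shrinks as components are added."""
    rng = np.random.default_rng(13)
    n, bins_n = 120, 800
    batch = rng.integers(0, 2, n).astype(float)
    f2 = rng.standard_normal(n)
    scores = np.column_stack([batch - batch.mean(), f2])
    loadings = rng.standard_normal((2, bins_n))
    depths = 38.0 * (1.0 + 0.08 * scores @ loadings) \
        + rng.normal(0, 0.2, (n, bins_n))
    m = BinDepthMatrix(samples=[f"s{i}" for i in range(n)],
                       bins=_bins(bins_n), depths=np.clip(depths, 0, None))
    tl = 3500.0 + 400.0 * (batch - batch.mean()) + rng.normal(0, 100, n)
    pcs = fit_batch_pcs(m, 2, seed=9)
    table = component_diagnostics(tl, pcs, labels={"batch": batch},
                                  grid=[0, 1, 2])
    r2 = table["r2_batch"].to_numpy()
    assert np.all(np.diff(r2) <= 1e-9)
    assert r2[-1] < r2[0]
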