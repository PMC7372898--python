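"""Synthetic cohort generator properties."""

import numpy as np
import pytest
from scipy import stats

from hegwas.gwas_plain import full_irls_oracle
from hegwas.synthetic import (SimConfig, generate, load_truth,
                              resample_scale, save_truth)


def test_reproducible_under_seed():
    a, ca = generate(SimConfig(N=40, M=30, seed=9, n_causal=3))
    b, cb = generate(SimConfig(N=40, M=30, seed=9, n_causal=3))
    assert np.array_equal(a.S, b.S) and np.array_equal(a.X, b.X) \
        and np.array_equal(a.y, b.y) and np.array_equal(ca, cb)
    c, _ = generate(SimConfig(N=40, M=30, seed=10, n_causal=3))
    assert not np.array_equal(a.S, c.S)


def test_genotype_marginals_hardy_weinberg():
    cfg = SimConfig(N=4000, M=5, maf_range=(0.3, 0.3), n_causal=0, seed=1)
    ds, _ = generate(cfg)
    assert set(np.unique(ds.S)) <= {0.0, 1.0, 2.0}
    q = 0.3
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    for j in range(5):
        counts = np.array([(ds.S[:, j] == g).sum() for g in (0, 1, 2)])
        chi2 = float(((counts - 4000 * expected) ** 2
                      / (4000 * expected)).sum())
        assert chi2 < stats.chi2.ppf(0.999, df=2)


def test_case_fraction_targeting():
    for frac in (0.1, 0.5, 0.9):
        ds, _ = generate(SimConfig(N=3000, M=10, n_causal=0,
                                   case_fraction=frac, seed=2))
        assert abs(ds.y.mean() - frac) < 0.04


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(case_fraction=0.95)
    with pytest.raises(ValueError):
        SimConfig(maf_range=(0.0, 0.4))
    with pytest.raises(ValueError):
        SimConfig(M=10, n_causal=11)


def test_null_pvalues_approximately_uniform():
    """With no causal SNPs the fully converged per-SNP logistic p-values
    pass a KS test against Uniform(0, 1)."""
    ds, _ = generate(SimConfig(N=245, M=150, n_causal=0, seed=5))
    p = full_irls_oracle(ds)
    stat = stats.kstest(p, "uniform")
    assert stat.pvalue > 0.01


def test_causal_snps_enriched():
    ds, causal = generate(SimConfig(N=245, M=300, n_causal=15,
                                    effect_size=0.8, seed=6))
    p = full_irls_oracle(ds)
    null = np.setdiff1d(np.arange(300), causal)
    hits = int((p[causal] < 0.01).sum())
    null_hits = int((p[null] < 0.01).sum())
    table = [[hits, len(causal) - hits],
             [null_hits, len(null) - null_hits]]
    enrich_p = stats.fisher_exact(table, alternative="greater").pvalue
    assert enrich_p < 1e-3
    assert null_hits / len(null) < 0.05


def test_resample_scale():
    ds, _ = generate(SimConfig(N=30, M=20, n_causal=0, seed=7))
    out = resample_scale(ds, 100, 50, seed=1)
    assert out.S.shape == (100, 50) and out.X.shape == (100, ds.k)
    assert len(set(out.ids)) == 50  # uniqueness suffixes
    # allele frequencies preserved in expectation
    freqs = [resample_scale(ds, 30, 20, seed=s).S.mean() for s in range(20)]
    assert abs(np.mean(freqs) - ds.S.mean()) < 0.05


def test_truth_roundtrip(tmp_path):
    causal = np.array([2, 5, 9])
    path = str(tmp_path / "truth.tsv")
    save_truth(path, 12, causal)
    assert np.array_equal(load_truth(path), causal)
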