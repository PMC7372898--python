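"""Synthetic GWAS cohorts with the structure the semi-parallel method assumes.

Genotypes are Binomial(2, maf) dosages, covariates standard normal, and the
phenotype is drawn from a TRUE logistic model (the exact sigmoid, not the
linear surrogate -- the approximation must face data it did not generate),
with the intercept tuned by bisection so the expected case fraction hits the
configured target.  A resampling scaler produces larger cohorts for
scalability runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gwas_plain import GwasDataset


@dataclass
class SimConfig:
    N: int = 245
    M: int = 2000
    K: int = 3
    maf_range: tuple = (0.05, 0.5)
    n_causal: int = 40           # 2% of the default M
    effect_size: float = 0.5     # log-odds per allele at causal SNPs
    theta_true: Optional[np.ndarray] = None   # covariate effects (length K)
    case_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf bounds must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.n_causal <= self.M):
            raise ValueError("n_causal must lie in [0, M]")
        if not (0.1 <= self.case_fraction <= 0.9):
            raise ValueError("case_fraction must lie in [0.1, 0.9]")
        if self.theta_true is None:
            self.theta_true = np.full(self.K, 0.2)
        self.theta_true = np.asarray(self.theta_true, dtype=np.float64)
        if self.theta_true.shape != (self.K,):
            raise ValueError("theta_true must have length K")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


def generate(cfg: SimConfig) -> tuple:
    """Returns (GwasDataset, causal_indices)."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, cfg.M)
    S = rng.binomial(2, maf[None, :], size=(cfg.N, cfg.M)).astype(np.float64)
    Xc = rng.standard_normal((cfg.N, cfg.K))
    X = np.column_stack([np.ones(cfg.N), Xc])
    causal = np.sort(rng.choice(cfg.M, size=cfg.n_causal, replace=False))
    beta = np.zeros(cfg.M)
    beta[causal] = cfg.effect_size
    lin = Xc @ cfg.theta_true + S @ beta

    def mean_case(theta0):
        return float(np.mean(_sigmoid(theta0 + lin)))

    lo_t, hi_t = -60.0, 60.0
    if not (mean_case(lo_t) <= cfg.case_fraction <= mean_case(hi_t)):
        raise ValueError("case_fraction unattainable for this configuration")
    for _ in range(200):
        mid = 0.5 * (lo_t + hi_t)
        if mean_case(mid) < cfg.case_fraction:
            lo_t = mid
        else:
            hi_t = mid
    theta0 = 0.5 * (lo_t + hi_t)
    y = (rng.uniform(size=cfg.N) < _sigmoid(theta0 + lin)).astype(np.float64)
    ids = [f"snp{j}" for j in range(cfg.M)]
    return GwasDataset(X, y, S, ids), causal


def resample_scale(ds: GwasDataset, N_out: int, M_out: int,
                   seed: int = 0) -> GwasDataset:
    """Scale a cohort by resampling rows (individuals) and SNP columns with
    replacement; SNP labels get uniqueness suffixes."""
    if ds.N == 0 or ds.M == 0:
        raise ValueError("source dataset is empty")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, ds.N, N_out)
    cols = rng.integers(0, ds.M, M_out)
    counts: dict = {}
    ids = []
    for c in cols:
        rep = counts.get(c, 0)
        counts[c] = rep + 1
        ids.append(f"{ds.ids[c]}_r{rep}")
    return GwasDataset(ds.X[rows], ds.y[rows], ds.S[np.ix_(rows, cols)], ids)


def save_truth(path: str, M: int, causal: np.ndarray) -> None:
    import pandas as pd
    causal_set = set(int(c) for c in causal)
    pd.DataFrame({
        "snp_index": np.arange(M),
        "causal": [int(j in causal_set) for j in range(M)],
    }).to_csv(path, sep="\t", index=False)


def load_truth(path: str) -> np.ndarray:
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    return df.loc[df["causal"] == 1, "snp_index"].to_numpy()
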