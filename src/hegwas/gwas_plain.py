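"""Plaintext reference implementation of the approximated semi-parallel GWAS.

The model: a logistic regression of a binary phenotype y on covariates X
(N x k, leading intercept column) is fitted once with a single gradient
step and a linear approximation of the sigmoid; every SNP column s of S is
then scored with a one-step weighted-least-squares update, all M SNPs in
parallel through the compact expression

    z_j = (1/det H) * (sum_i w_i zeta*_i s*_ij) / sqrt(sum_i w_i s*_ij^2)

with H = X^T W X, zeta* = detH*zeta - X adj(H) X^T W zeta and
S* = detH*S - X adj(H) X^T W S.  The matrix inverse is realised through
Cramer's rule (adjoint and determinant only), divisions and the square
root being deferred to the client.  Exact per-SNP oracles and a fully
converged IRLS baseline are provided for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Optional

import numpy as np
from scipy.stats import norm

SIGMOID_SLOPE = 0.15625       # linear least-squares fit of the sigmoid
DEFAULT_ALPHA = 0.015         # gradient-descent learning rate


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class GwasDataset:
    """Covariates X (leading intercept column), binary phenotype y, and
    SNP dosage matrix S with entries in {0, 1, 2}."""

    X: np.ndarray
    y: np.ndarray
    S: np.ndarray
    ids: Optional[list] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.S = np.asarray(self.S, dtype=np.float64)
        if self.X.ndim != 2 or self.y.ndim != 1 or self.S.ndim != 2:
            raise ValueError("X and S must be matrices, y a vector")
        N = self.X.shape[0]
        if self.y.shape[0] != N or self.S.shape[0] != N:
            raise ValueError("X, y, S must agree on the number of individuals")
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("phenotype must be binary")
        if not np.all(np.isin(self.S, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must lie in {0, 1, 2}")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept")
        if self.ids is None:
            self.ids = [f"snp{j}" for j in range(self.S.shape[1])]

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def M(self) -> int:
        return self.S.shape[1]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def K(self) -> int:
        return self.k - 1


@dataclass
class CovariateFit:
    theta: Optional[np.ndarray] = None
    alpha: float = DEFAULT_ALPHA
    iterations: int = 1


@dataclass
class SemiParallelResult:
    detH: float
    adjH: np.ndarray
    zeta_star: np.ndarray
    numerators: np.ndarray
    denominators: np.ndarray
    z: np.ndarray
    p: np.ndarray
    degenerate: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# Model pieces
# ---------------------------------------------------------------------------

def sigmoid_approx(x):
    """Linear sigmoid surrogate 0.5 + 0.15625 x."""
    return 0.5 + SIGMOID_SLOPE * np.asarray(x, dtype=np.float64)


def fit_covariates(ds: GwasDataset, fit: Optional[CovariateFit] = None
                   ) -> CovariateFit:
    """Gradient-descent logistic fit with the linear sigmoid:
    theta^{t+1} = theta^t + alpha X^T (y - rho^t), theta^0 = 0."""
    fit = CovariateFit() if fit is None else fit
    if fit.iterations < 1:
        raise ValueError("need at least one iteration")
    theta = np.zeros(ds.k)
    for _ in range(fit.iterations):
        rho = sigmoid_approx(ds.X @ theta)
        theta = theta + fit.alpha * (ds.X.T @ (ds.y - rho))
    fit.theta = theta
    return fit


def rho_closed_form(ds: GwasDataset, alpha: float = DEFAULT_ALPHA
                    ) -> np.ndarray:
    """One-step rho without materialising theta:
    rho = 1/2 + 0.15625 * alpha * X X^T (y - 1/2)."""
    return 0.5 + SIGMOID_SLOPE * alpha * (ds.X @ (ds.X.T @ (ds.y - 0.5)))


def weights(rho: np.ndarray) -> np.ndarray:
    rho = np.asarray(rho, dtype=np.float64)
    return rho * (1.0 - rho)


# degree-8 Taylor coefficients of zeta(p, y) = log(p/(1-p)) + (y-p)/(p(1-p))
# around p = 1/2, in d = p - 1/2; even coefficients depend on y, odd ones
# (beyond the vanishing linear term) are constants
def zeta_coefficients(y):
    y = np.asarray(y, dtype=np.float64)
    zero = np.zeros_like(y)
    return [
        -2.0 + 4.0 * y,
        zero,
        -8.0 + 16.0 * y,
        zero - 32.0 / 3.0,
        -32.0 + 64.0 * y,
        zero - 256.0 / 5.0,
        -128.0 + 256.0 * y,
        zero - 1536.0 / 7.0,
        -512.0 + 1024.0 * y,
    ]


def zeta_taylor(rho, y):
    """Degree-8 Taylor surrogate for the working response zeta."""
    rho = np.asarray(rho, dtype=np.float64)
    d = rho - 0.5
    coeffs = zeta_coefficients(y)
    acc = np.zeros_like(d) + coeffs[-1]
    for c in reversed(coeffs[:-1]):
        acc = acc * d + c
    return acc


# ---------------------------------------------------------------------------
# Cramer inversion
# ---------------------------------------------------------------------------

def _minors2(H: np.ndarray) -> dict:
    """All 2x2 minors M[(r,s),(c,d)] = H[r,c]H[s,d] - H[r,d]H[s,c]."""
    k = H.shape[0]
    out = {}
    for (r, s) in combinations(range(k), 2):
        for (c, d) in combinations(range(k), 2):
            out[(r, s, c, d)] = H[r, c] * H[s, d] - H[r, d] * H[s, c]
    return out


def _cofactor3(H, m2, rows, cols):
    """3x3 determinant from shared 2x2 minors (expansion along rows[0])."""
    r0, r1, r2 = rows
    c0, c1, c2 = cols
    return (H[r0, c0] * m2[(r1, r2, c1, c2)]
            - H[r0, c1] * m2[(r1, r2, c0, c2)]
            + H[r0, c2] * m2[(r1, r2, c0, c1)])


def adjoint_det(H: np.ndarray) -> tuple:
    """Adjoint and determinant with H @ adj = det * I.

    For k = 4 the closed form shares the 2x2 minors between the Laplace
    determinant (complementary-minor products, so 3-in-series products are
    grouped as binary trees of depth 2) and the sixteen cofactors -- the
    same expression tree the encrypted evaluator uses.  Other sizes fall
    back to a generic cofactor expansion.
    """
    H = np.asarray(H, dtype=np.float64)
    k = H.shape[0]
    if H.shape != (k, k):
        raise ValueError("H must be square")
    if k == 1:
        return np.array([[1.0]]), float(H[0, 0])
    if k == 4:
        m2 = _minors2(H)
        det = 0.0
        for (c, d) in combinations(range(4), 2):
            comp = tuple(sorted(set(range(4)) - {c, d}))
            sign = (-1.0) ** (c + d + 1)
            det += sign * m2[(0, 1, c, d)] * m2[(2, 3) + comp]
        adj = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                rows = tuple(r for r in range(4) if r != j)
                cols = tuple(c for c in range(4) if c != i)
                adj[i, j] = (-1.0) ** (i + j) * _cofactor3(H, m2, rows, cols)
        return adj, float(det)
    # generic cofactor fallback
    adj = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            sub = np.delete(np.delete(H, j, axis=0), i, axis=1)
            adj[i, j] = (-1.0) ** (i + j) * np.linalg.det(sub)
    det = float(np.sum(H[0] * adj[:, 0]))
    return adj, det


# ---------------------------------------------------------------------------
# Semi-parallel scoring
# ---------------------------------------------------------------------------

def p_values(z: np.ndarray) -> np.ndarray:
    """Two-sided standard-normal tail probabilities 2(1 - Phi(|z|))."""
    return 2.0 * norm.sf(np.abs(np.asarray(z, dtype=np.float64)))


def semi_parallel_z(ds: GwasDataset, theta: np.ndarray,
                    degeneracy_tol: float = 1e-12) -> SemiParallelResult:
    """All-SNP one-step Wald scores via the compact division-free algebra."""
    X, y, S = ds.X, ds.y, ds.S
    rho = sigmoid_approx(X @ theta)
    w = weights(rho)
    zeta = zeta_taylor(rho, y)
    H = X.T @ (w[:, None] * X)
    adj, det = adjoint_det(H)
    w_zeta = w * zeta
    zeta_star = det * zeta - X @ (adj @ (X.T @ w_zeta))
    WS = w[:, None] * S
    S_star = det * S - X @ (adj @ (X.T @ WS))
    num = S_star.T @ (w * zeta_star)
    den = np.einsum("ij,ij->j", S_star * w[:, None], S_star)
    degenerate = den <= degeneracy_tol * max(1.0, float(np.max(np.abs(den))))
    z = np.zeros(ds.M)
    good = ~degenerate
    z[good] = num[good] / (det * np.sqrt(den[good]))
    p = p_values(z)
    p[degenerate] = 1.0
    return SemiParallelResult(det, adj, zeta_star, num, den, z, p, degenerate)


def per_snp_oracle(ds: GwasDataset, theta: np.ndarray) -> np.ndarray:
    """Direct per-SNP evaluation with explicit linear solves: for each SNP,
    project it W-orthogonally off the covariates and form the Wald ratio
    z_j = s~^T W zeta / sqrt(s~^T W s~)."""
    X, y = ds.X, ds.y
    rho = sigmoid_approx(X @ theta)
    w = weights(rho)
    zeta = zeta_taylor(rho, y)
    H = X.T @ (w[:, None] * X)
    z = np.zeros(ds.M)
    for j in range(ds.M):
        s = ds.S[:, j]
        u = np.linalg.solve(H, X.T @ (w * s))
        s_t = s - X @ u
        den = float(s_t @ (w * s_t))
        if den <= 1e-12:
            continue
        z[j] = float(s_t @ (w * zeta)) / np.sqrt(den)
    return z


def full_irls_oracle(ds: GwasDataset, max_iter: int = 50,
                     tol: float = 1e-10) -> np.ndarray:
    """Fully converged per-SNP logistic regression (true sigmoid, IRLS);
    returns the Wald p-value of the SNP coefficient.  The accuracy baseline
    the approximate pipeline is scored against."""
    N, k = ds.X.shape
    p_out = np.ones(ds.M)
    for j in range(ds.M):
        A = np.column_stack([ds.X, ds.S[:, j]])
        beta = np.zeros(k + 1)
        ok = False
        for _ in range(max_iter):
            eta = np.clip(A @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            wts = mu * (1.0 - mu)
            if np.max(wts) < 1e-12:
                break
            grad = A.T @ (ds.y - mu)
            Hm = A.T @ (wts[:, None] * A)
            try:
                step = np.linalg.solve(Hm, grad)
            except np.linalg.LinAlgError:
                break
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                ok = True
                break
        if not ok:
            continue
        try:
            cov = np.linalg.inv(Hm)
        except np.linalg.LinAlgError:
            continue
        se = np.sqrt(max(cov[-1, -1], 0.0))
        if se > 0:
            p_out[j] = float(2.0 * norm.sf(abs(beta[-1]) / se))
    return p_out


# ---------------------------------------------------------------------------
# TSV / VCF plumbing
# ---------------------------------------------------------------------------

def save_dataset(ds: GwasDataset, prefix: str) -> None:
    """Write <prefix>.cov.tsv, <prefix>.phe.tsv, <prefix>.gen.tsv."""
    import pandas as pd
    idx = [f"ind{i}" for i in range(ds.N)]
    cov = pd.DataFrame(ds.X[:, 1:], index=idx,
                       columns=[f"cov{c}" for c in range(1, ds.k)])
    cov.to_csv(prefix + ".cov.tsv", sep="\t", index_label="individual")
    phe = pd.DataFrame({"phenotype": ds.y.astype(int)}, index=idx)
    phe.to_csv(prefix + ".phe.tsv", sep="\t", index_label="individual")
    gen = pd.DataFrame(ds.S.astype(int), index=idx, columns=ds.ids)
    gen.to_csv(prefix + ".gen.tsv", sep="\t", index_label="individual")


def load_dataset(prefix: str) -> GwasDataset:
    import pandas as pd
    cov = pd.read_csv(prefix + ".cov.tsv", sep="\t", index_col=0)
    phe = pd.read_csv(prefix + ".phe.tsv", sep="\t", index_col=0)
    gen = pd.read_csv(prefix + ".gen.tsv", sep="\t", index_col=0)
    X = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=np.float64)])
    return GwasDataset(X, phe["phenotype"].to_numpy(dtype=np.float64),
                       gen.to_numpy(dtype=np.float64), list(gen.columns))


def save_results(path: str, ids, result: SemiParallelResult) -> None:
    import pandas as pd
    pd.DataFrame({
        "snp_id": ids,
        "numerator": result.numerators,
        "denominator": result.denominators,
        "detH": result.detH,
        "z": result.z,
        "p": result.p,
    }).to_csv(path, sep="\t", index=False)


def load_vcf_dosages(path: str) -> tuple:
    """Minimal VCF GT-field import: returns (S, ids) with dosages {0,1,2}."""
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                continue
            fmt = parts[8].split(":")
            gt_idx = fmt.index("GT")
            dos = []
            for sample in parts[9:]:
                gt = sample.split(":")[gt_idx].replace("|", "/")
                alleles = [a for a in gt.split("/") if a in ("0", "1")]
                dos.append(float(sum(int(a) for a in alleles)))
            ids.append(parts[2] if parts[2] != "." else f"{parts[0]}:{parts[1]}")
            rows.append(dos)
    return np.array(rows, dtype=np.float64).T, ids
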