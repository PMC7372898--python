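"""Plaintext semi-parallel algebra: surrogates, Cramer inversion, oracles,
TSV round trips."""

import numpy as np
import pytest
import sympy as sp

from hegwas.gwas_plain import (GwasDataset, adjoint_det, fit_covariates,
                               load_dataset, p_values, per_snp_oracle,
                               rho_closed_form, save_dataset, save_results,
                               semi_parallel_z, sigmoid_approx,
                               zeta_coefficients, zeta_taylor)
from hegwas.synthetic import SimConfig, generate


@pytest.fixture(scope="module")
def cohort():
    ds, _ = generate(SimConfig(N=60, M=40, K=3, n_causal=4, seed=11))
    return ds


def test_zeta_coefficients_match_symbolic_differentiation():
    """The degree-8 coefficients of zeta(p, y) = log(p/(1-p)) + (y-p)/(p(1-p))
    around p = 1/2 follow from symbolic differentiation, including the
    constant odd terms -32/3, -256/5 and -1536/7."""
    p, y, d = sp.symbols("p y d")
    zeta = sp.log(p / (1 - p)) + (y - p) / (p * (1 - p))
    series = sp.series(zeta.subs(p, sp.Rational(1, 2) + d), d, 0, 9).removeO()
    poly = sp.Poly(sp.expand(series), d)
    y_val = sp.Rational(3, 7)  # arbitrary rational probe for the y-terms
    got = zeta_coefficients(float(y_val))
    for degree in range(9):
        want = poly.coeff_monomial(d ** degree).subs(y, y_val)
        assert sp.Rational(float(got[degree])).limit_denominator(10 ** 12) \
            == sp.nsimplify(want), f"degree {degree}"
    sym = [poly.coeff_monomial(d ** k) for k in range(9)]
    assert sym[3] == sp.Rational(-32, 3)
    assert sym[5] == sp.Rational(-256, 5)
    assert sym[7] == sp.Rational(-1536, 7)


def test_zeta_taylor_evaluates_series(cohort):
    rho = rho_closed_form(cohort)
    z1 = zeta_taylor(rho, cohort.y)
    d = rho - 0.5
    c = zeta_coefficients(cohort.y)
    direct = sum(ci * d ** i for i, ci in enumerate(c))
    assert np.allclose(z1, direct, atol=1e-12)


def test_fit_covariates_is_one_gradient_step(cohort):
    fit = fit_covariates(cohort)
    rho0 = sigmoid_approx(cohort.X @ np.zeros(cohort.k))
    want = fit.alpha * (cohort.X.T @ (cohort.y - rho0))
    assert np.allclose(fit.theta, want)
    assert np.allclose(rho_closed_form(cohort),
                       sigmoid_approx(cohort.X @ fit.theta))


def test_adjoint_det_identity(rng):
    for _ in range(5):
        H = rng.normal(size=(4, 4))
        H = H @ H.T + 4 * np.eye(4)
        adj, det = adjoint_det(H)
        assert np.allclose(H @ adj, det * np.eye(4), rtol=1e-10)
        assert np.isclose(det, np.linalg.det(H), rtol=1e-10)
        assert np.allclose(adj, det * np.linalg.inv(H), rtol=1e-8)


def test_semi_parallel_matches_per_snp_oracle(cohort):
    fit = fit_covariates(cohort)
    res = semi_parallel_z(cohort, fit.theta)
    oracle = per_snp_oracle(cohort, fit.theta)
    assert np.max(np.abs(res.z - oracle)) < 1e-8


def test_degenerate_snp_flagged():
    ds, _ = generate(SimConfig(N=30, M=5, K=2, n_causal=0, seed=3))
    # a SNP colinear with the intercept has no W-orthogonal component
    ds.S[:, 2] = 1.0
    res = semi_parallel_z(ds, fit_covariates(ds).theta)
    assert res.degenerate[2]
    assert res.p[2] == 1.0 and res.z[2] == 0.0


def test_p_values():
    assert np.isclose(p_values(np.array([0.0]))[0], 1.0)
    assert np.isclose(p_values(np.array([1.959963985]))[0], 0.05, atol=1e-6)
    assert p_values(np.array([5.0]))[0] < 1e-6


def test_dataset_and_results_roundtrip(tmp_path, cohort):
    prefix = str(tmp_path / "cohort")
    save_dataset(cohort, prefix)
    back = load_dataset(prefix)
    assert np.array_equal(back.S, cohort.S)
    assert np.array_equal(back.y, cohort.y)
    assert np.allclose(back.X, cohort.X)
    assert back.ids == cohort.ids
    res = semi_parallel_z(cohort, fit_covariates(cohort).theta)
    out = str(tmp_path / "res.tsv")
    save_results(out, cohort.ids, res)
    import pandas as pd
    df = pd.read_csv(out, sep="\t")
    assert np.allclose(df["z"], res.z)
    assert np.allclose(df["p"], res.p)
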