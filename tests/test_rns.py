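"""Ring-layer exactness tests: modular kernels, NTT, rescaling."""

import random

import numpy as np
import pytest

import hegwas.rns as rns
from hegwas.rns import (COEFF, EVAL, RnsPoly, addmod, apply_automorphism,
                        drop_limb, generate_modulus_chain, intt, mulmod,
                        negacyclic_convolve_reference, ntt, poly_add,
                        poly_mul, rescale_poly, submod)


@pytest.mark.parametrize("bits", [45, 50, 51])
def test_modular_kernels_exact(bits):
    """Vectorized mulmod/addmod/submod agree with Python big-int arithmetic
    up to the documented 51-bit modulus bound, including the broadcast
    (rows, 1) operand shape the limb layer uses."""
    rng = random.Random(bits)
    rows, cols = 4, 32
    # arbitrary odd moduli just below 2^bits (exactness needs m < 2^51,
    # not primality)
    m = np.array([[(1 << bits) - d] for d in (55, 87, 99, 165)],
                 dtype=np.uint64)
    assert all(int(v) < (1 << 51) for v in m.ravel())
    a = np.array([[rng.randrange(int(mi)) for _ in range(cols)]
                  for mi in m.ravel()], dtype=np.uint64)
    b = np.array([[rng.randrange(int(mi)) for _ in range(cols)]
                  for mi in m.ravel()], dtype=np.uint64)
    for op, ref in ((mulmod, lambda x, y, q: x * y % q),
                    (addmod, lambda x, y, q: (x + y) % q),
                    (submod, lambda x, y, q: (x - y) % q)):
        got = op(a, b, m)
        want = np.array([[ref(int(x), int(y), int(q)) for x, y in zip(ra, rb)]
                         for ra, rb, q in zip(a, b, m.ravel())],
                        dtype=np.uint64)
        assert np.array_equal(got, want)
    # broadcast second operand of shape (rows, 1)
    b1 = b[:, :1]
    got = mulmod(a, b1, m)
    want = np.array([[int(x) * int(rb[0]) % int(q) for x in ra]
                     for ra, rb, q in zip(a, b1, m.ravel())], dtype=np.uint64)
    assert np.array_equal(got, want)


def test_chain_primes_ntt_friendly():
    chain = generate_modulus_chain(30, 64, 6)
    assert len(set(chain.primes)) == 6
    for q in chain.primes:
        assert q % (2 * 64) == 1
        assert abs(q - 2 ** 30) < 2 ** 20


def test_ntt_intt_roundtrip():
    chain = generate_modulus_chain(30, 64, 4)
    rng = random.Random(0)
    coeffs = [rng.randrange(chain.Q(4)) for _ in range(64)]
    a = RnsPoly.from_int_coeffs(chain, 4, coeffs)
    back = intt(ntt(a.copy()))
    assert np.array_equal(back.residues, a.residues)


@pytest.mark.parametrize("p,n,L", [(30, 8, 3), (45, 16, 3), (50, 16, 2)])
def test_ntt_multiplication_vs_schoolbook(p, n, L):
    """poly_mul through the NTT equals the O(n^2) big-int negacyclic
    convolution oracle, limb by limb."""
    chain = generate_modulus_chain(p, n, L)
    rng = random.Random(7)
    Q = chain.Q(L)
    ca = [rng.randrange(Q) for _ in range(n)]
    cb = [rng.randrange(Q) for _ in range(n)]
    a = ntt(RnsPoly.from_int_coeffs(chain, L, ca))
    b = ntt(RnsPoly.from_int_coeffs(chain, L, cb))
    prod = intt(poly_mul(a, b))
    for limb in range(L):
        q = int(chain.primes[limb])
        want = negacyclic_convolve_reference(ca, cb, q)
        assert [int(x) for x in prod.residues[limb]] == want


def test_fft_kernel_matches_numpy_fallback(monkeypatch):
    """The numba butterfly kernel and the pure-numpy fallback produce
    bit-identical NTTs."""
    if not rns._HAVE_NUMBA:
        # numpy fallback is the only path; nothing to cross-check
        return
    chain = generate_modulus_chain(45, 256, 7)
    rng = random.Random(3)
    coeffs = [rng.randrange(chain.Q(7)) for _ in range(256)]
    a = RnsPoly.from_int_coeffs(chain, 7, coeffs)
    fast = ntt(a.copy())
    monkeypatch.setattr(rns, "_HAVE_NUMBA", False)
    slow = ntt(a.copy())
    assert np.array_equal(fast.residues, slow.residues)
    back = intt(fast)
    assert np.array_equal(back.residues, a.residues)


def test_rescale_matches_multiprecision_rounding_oracle():
    """RNS rescale equals the rounded quotient round(x / q_l) computed in
    exact big-int arithmetic."""
    for (p, n, L) in [(30, 16, 4), (45, 32, 5)]:
        chain = generate_modulus_chain(p, n, L)
        rng = random.Random(p)
        Q, ql, Qm = chain.Q(L), int(chain.primes[L - 1]), chain.Q(L - 1)
        coeffs = [rng.randrange(Q) for _ in range(n)]
        a = ntt(RnsPoly.from_int_coeffs(chain, L, coeffs))
        out = intt(rescale_poly(a)).to_int_coeffs(centered=False)
        oracle = [((x + ql // 2) // ql) % Qm for x in coeffs]
        assert [int(v) for v in out] == oracle


def test_rescale_counts_ell_native_ntts():
    """One rescale at level l performs exactly l native NTTs (1 inverse on
    the top limb + l-1 forward on the derived term)."""
    chain = generate_modulus_chain(30, 16, 5)
    rng = random.Random(1)
    coeffs = [rng.randrange(chain.Q(5)) for _ in range(16)]
    a = ntt(RnsPoly.from_int_coeffs(chain, 5, coeffs))
    before = chain.counters.native_ntts
    rescale_poly(a)
    assert chain.counters.native_ntts - before == 5


def test_drop_limb_preserves_value():
    chain = generate_modulus_chain(30, 16, 4)
    rng = random.Random(2)
    coeffs = [rng.randrange(chain.Q(2)) for _ in range(16)]
    a = RnsPoly.from_int_coeffs(chain, 4, coeffs)
    d = drop_limb(a, 2)
    assert d.level == 2
    assert [int(x) % chain.Q(2) for x in d.to_int_coeffs(centered=False)] \
        == [x % chain.Q(2) for x in coeffs]
    with pytest.raises(ValueError):
        drop_limb(a, 4)


def test_automorphism_composition():
    chain = generate_modulus_chain(30, 16, 3)
    rng = random.Random(4)
    coeffs = [rng.randrange(chain.Q(3)) for _ in range(16)]
    a = ntt(RnsPoly.from_int_coeffs(chain, 3, coeffs))
    g1, g2 = 5, 9
    left = apply_automorphism(apply_automorphism(a, g1), g2)
    right = apply_automorphism(a, (g1 * g2) % (2 * 16))
    assert np.array_equal(left.residues, right.residues)


def test_poly_add_matches_bigint():
    chain = generate_modulus_chain(30, 16, 3)
    rng = random.Random(5)
    Q = chain.Q(3)
    ca = [rng.randrange(Q) for _ in range(16)]
    cb = [rng.randrange(Q) for _ in range(16)]
    out = poly_add(RnsPoly.from_int_coeffs(chain, 3, ca),
                   RnsPoly.from_int_coeffs(chain, 3, cb))
    assert [int(v) for v in out.to_int_coeffs(centered=False)] \
        == [(x + y) % Q for x, y in zip(ca, cb)]
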