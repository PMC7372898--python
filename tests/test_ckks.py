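"""Scheme-layer tests: encoding, encryption, homomorphic ops, noise bounds,
key compression and operation accounting."""

from fractions import Fraction

import numpy as np
import pytest

from hegwas.ckks import (CkksContext, noise_bounds, sizeof_ciphertext,
                         sizeof_poly, sizeof_secret_key, sizeof_switchkey)
from hegwas.rns import generate_modulus_chain

DELTA = Fraction(2) ** 30


def _err(ctx, ct, want):
    return float(np.max(np.abs(np.real(ctx.decrypt_vector(ct))
                               - np.asarray(want))))


def test_encode_decode_roundtrip(small_ctx):
    v = np.linspace(-1.5, 1.5, 32)
    out = small_ctx.decode(small_ctx.encode(v, 5, DELTA))
    assert np.max(np.abs(np.real(out) - v)) < 1e-7


def test_encrypt_decrypt_within_clean_bound(small_ctx):
    v = np.linspace(-1, 1, 32)
    ct = small_ctx.encrypt(small_ctx.encode(v, 5, DELTA))
    bound = noise_bounds("clean", n=64) / float(DELTA)
    assert _err(small_ctx, ct, v) < bound


def test_add_sub_cadd(small_ctx):
    a, b = np.linspace(-1, 1, 32), np.linspace(0.5, -0.5, 32)
    ca = small_ctx.encrypt(small_ctx.encode(a, 5, DELTA))
    cb = small_ctx.encrypt(small_ctx.encode(b, 5, DELTA))
    assert _err(small_ctx, small_ctx.add(ca, cb), a + b) < 1e-5
    assert _err(small_ctx, small_ctx.sub(ca, cb), a - b) < 1e-5
    assert _err(small_ctx, small_ctx.cadd(ca, 0.25), a + 0.25) < 1e-5


def test_mult_relin_rescale_circuit(small_ctx):
    """(a*b) with relinearization and rescale; then a second product to
    exercise the scale bookkeeping two levels deep."""
    ctx = small_ctx
    a, b = np.linspace(-1, 1, 32), np.linspace(0.2, 0.9, 32)
    ca = ctx.encrypt(ctx.encode(a, 5, DELTA))
    cb = ctx.encrypt(ctx.encode(b, 5, DELTA))
    prod = ctx.mult(ca, cb)
    assert prod.size == 3 and prod.scale == DELTA * DELTA
    rel = ctx.relinearize(prod)
    assert rel.size == 2
    res = ctx.rescale(rel)
    assert res.level == 4
    assert res.scale == DELTA * DELTA / int(ctx.chain.primes[4])
    assert _err(ctx, res, a * b) < 1e-4
    sq = ctx.rescale(ctx.relinearize(ctx.mult(res, ctx.drop_to_level(ca, 4))))
    assert _err(ctx, sq, a * a * b) < 1e-3


def test_lazy_relinearization_decrypts_large_ciphertexts(small_ctx):
    """Unrelinearized products grow in size and still decrypt correctly:
    decryption evaluates the polynomial in the secret."""
    ctx = small_ctx
    a = np.linspace(0.1, 1, 32)
    ca = ctx.encrypt(ctx.encode(a, 5, DELTA))
    c2 = ctx.mult(ca, ca)              # size 3
    c3 = ctx.mult(c2, ca)              # size 4
    assert (c2.size, c3.size) == (3, 4)
    assert _err(ctx, c3, a ** 3 * float(DELTA) ** 0) < 1e-3
    # sum of size-3 ciphertexts relinearized once
    s = ctx.add(c2, c2)
    r = ctx.relinearize(s)
    assert r.size == 2 and _err(ctx, r, 2 * a * a) < 1e-3


def test_rotation_and_hoisting(small_ctx):
    ctx = small_ctx
    v = np.arange(32, dtype=np.float64) / 32
    ct = ctx.encrypt(ctx.encode(v, 5, DELTA * DELTA))  # pre-rescale scale
    for off in (1, 4, -4):
        got = np.real(ctx.decrypt_vector(ctx.rescale(ctx.rotate(ct, off))))
        assert np.max(np.abs(got - np.roll(v, -off))) < 1e-5
    comps = ctx.hoist_decompose(ct)
    h = ctx.rescale(ctx.hoisted_rotate(ct, comps, 2))
    assert np.max(np.abs(np.real(ctx.decrypt_vector(h))
                         - np.roll(v, -2))) < 1e-5


def test_rotation_at_base_scale_suffers_ksw_noise(small_ctx):
    """The single-digit key-switch noise is additive and large; rotating at
    the base scale shows it, rotating at a pre-rescale scale then rescaling
    buries it -- the pipeline's rotation policy."""
    ctx = small_ctx
    v = np.linspace(-1, 1, 32)
    base = ctx.encrypt(ctx.encode(v, 5, DELTA))
    boosted = ctx.encrypt(ctx.encode(v, 5, DELTA * DELTA))
    err_base = _err(ctx, ctx.rotate(base, 1), np.roll(v, -1))
    err_resc = _err(ctx, ctx.rescale(ctx.rotate(boosted, 1)), np.roll(v, -1))
    assert err_resc < err_base / 100
    ksw = noise_bounds("ksw", n=64, q_top=float(ctx.chain.primes[4]),
                       w=float(ctx.chain.primes[4]))
    assert err_base < 10 * ksw / float(DELTA)


def test_key_switch_costs_ell_squared_ntts(small_ctx):
    """Criterion instrumentation at the scheme layer: one key switch at
    level l costs exactly l^2 native NTTs; a rescale costs l per
    polynomial."""
    ctx = small_ctx
    v = np.linspace(-1, 1, 32)
    for lv in (5, 3):
        ct = ctx.encrypt(ctx.encode(v, lv, DELTA))
        before = ctx.counters.native_ntts
        ctx.rotate(ct, 1)
        assert ctx.counters.native_ntts - before == lv * lv
    ct = ctx.encrypt(ctx.encode(v, 4, DELTA))
    before = ctx.counters.native_ntts
    ctx.rescale(ctx.mult(ct, ct))      # size-3 ciphertext at level 4
    assert ctx.counters.native_ntts - before == 3 * 4


def test_switch_keys_generated_and_used_at_lower_levels(small_chain):
    ctx = CkksContext(small_chain, seed=1)
    ctx.keygen(rotation_indices=(1,), relin_powers=(2,),
               rotation_levels={1: 3}, relin_levels={2: 4})
    assert ctx.keys.rot_keys[1].stored_level == 3
    assert ctx.keys.evk[2].stored_level == 4
    v = np.linspace(-1, 1, 32)
    ct = ctx.encrypt(ctx.encode(v, 3, DELTA * DELTA))
    got = np.real(ctx.decrypt_vector(ctx.rescale(ctx.rotate(ct, 1))))
    assert np.max(np.abs(got - np.roll(v, -1))) < 1e-5
    ct4 = ctx.encrypt(ctx.encode(v, 4, DELTA))
    r = ctx.rescale(ctx.relinearize(ctx.mult(ct4, ct4)))
    assert np.max(np.abs(np.real(ctx.decrypt_vector(r)) - v * v)) < 1e-4
    # the compressed key cannot serve a higher level
    ct5 = ctx.encrypt(ctx.encode(v, 5, DELTA))
    with pytest.raises(ValueError):
        ctx.rotate(ct5, 1)


def test_sizeof_helpers(small_chain):
    assert sizeof_poly(5, small_chain) == 5 * 64 * 8
    assert sizeof_ciphertext(5, small_chain) == 2 * 5 * 64 * 8
    assert sizeof_ciphertext(5, small_chain, n_polys=3) == 3 * 5 * 64 * 8
    assert sizeof_switchkey(5, small_chain) == 2 * 5 * 5 * 64 * 8
    assert sizeof_secret_key(small_chain) == 2 * 5 * 64 * 8


def test_cmult_requires_matching_level(small_ctx):
    ctx = small_ctx
    v = np.linspace(-1, 1, 32)
    ct = ctx.encrypt(ctx.encode(v, 4, DELTA))
    with pytest.raises(ValueError):
        ctx.cmult(ct, ctx.encode(v, 5, DELTA))


def test_deterministic_under_seed(small_chain):
    outs = []
    for _ in range(2):
        ctx = CkksContext(small_chain, seed=42)
        ctx.keygen(relin_powers=(2,))
        ct = ctx.encrypt(ctx.encode(np.linspace(-1, 1, 32), 5, DELTA))
        outs.append([p.residues.copy() for p in ct.polys])
    for a, b in zip(*outs):
        assert np.array_equal(a, b)
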