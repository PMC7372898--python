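"""Slot-layout and conversion tests."""

from fractions import Fraction

import numpy as np
import pytest

from hegwas.ckks import CkksContext
from hegwas.packing import (MatrixLayout, convert_method1, convert_method2,
                            convert_method3, fill_clone, fold_sum,
                            pack_matrix, pack_transpose, pack_vector_colclone,
                            place, required_rotations_convert,
                            required_rotations_fill, required_rotations_fold,
                            sum_row_vec, unpack_matrix, unpack_transpose,
                            unpack_vector_colclone)
from hegwas.rns import generate_modulus_chain

DELTA = Fraction(2) ** 30


def test_pack_unpack_roundtrips(rng):
    X = rng.normal(size=(5, 3))
    assert np.allclose(unpack_matrix(pack_matrix(X), 5, 3), X)
    assert np.allclose(unpack_transpose(pack_transpose(X), 5, 3), X)
    y = rng.normal(size=7)
    assert np.allclose(unpack_vector_colclone(
        pack_vector_colclone(y, 3), 7, 3), y)


def test_pack_matrix_doc_examples():
    X = np.array([[1.0, 2.0], [3.0, 4.0]])
    assert pack_matrix(X).tolist() == [1, 2, 1, 2, 3, 4, 3, 4]
    assert pack_transpose(X).tolist() == [1, 1, 2, 2, 3, 3, 4, 4]
    assert pack_vector_colclone(np.array([5.0, 6.0]), 2).tolist() \
        == [5, 5, 5, 5, 6, 6, 6, 6]


def test_place_checks_capacity():
    with pytest.raises(ValueError):
        place(np.ones(40), 32)
    out = place(np.ones(8), 32)
    assert out[:8].sum() == 8 and out[8:].sum() == 0


@pytest.fixture(scope="module")
def pack_ctx():
    chain = generate_modulus_chain(30, 64, 6)
    ctx = CkksContext(chain, seed=0)
    layout = MatrixLayout("col-clone", 3, 2, ctx.n_slots)
    offs = set()
    for m in (1, 2, 3):
        offs |= required_rotations_convert(m, ctx.n_slots, layout)
    offs |= required_rotations_fold(ctx.n_slots, 1)
    offs |= required_rotations_fill(ctx.n_slots, 4)
    ctx.keygen(rotation_indices=sorted(offs), relin_powers=(2,))
    return ctx, layout


def test_fold_sum_replicates_total(pack_ctx):
    ctx, _ = pack_ctx
    v = np.zeros(ctx.n_slots)
    v[:8] = np.arange(1.0, 9.0)
    ct = ctx.encrypt(ctx.encode(v, ctx.chain.L, DELTA * DELTA))
    out = ctx.rescale(fold_sum(ctx, ct, 1))
    got = np.real(ctx.decrypt_vector(out))
    assert np.max(np.abs(got - v.sum())) < 1e-4


def test_fill_clone_periodizes(pack_ctx):
    ctx, _ = pack_ctx
    v = np.zeros(ctx.n_slots)
    v[:4] = [1.0, 2.0, 3.0, 4.0]
    ct = ctx.encrypt(ctx.encode(v, ctx.chain.L, DELTA * DELTA))
    got = np.real(ctx.decrypt_vector(ctx.rescale(fill_clone(ctx, ct, 4))))
    assert np.max(np.abs(got - np.tile(v[:4], ctx.n_slots // 4))) < 1e-4


def test_sum_row_vec_on_row_clone(pack_ctx):
    ctx, layout = pack_ctx
    X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    vec = place(pack_matrix(X), ctx.n_slots)
    ct = ctx.encrypt(ctx.encode(vec, ctx.chain.L, DELTA * DELTA))
    got = np.real(ctx.decrypt_vector(ctx.rescale(sum_row_vec(ctx, ct,
                                                             layout))))
    # valid at the first slot of every length-k row segment; the final slot
    # of each block wraps into the next row and is not asserted
    want = np.repeat(X.sum(axis=1), 4)
    first = np.arange(12) % layout.k == 0
    assert np.max(np.abs(got[:12][first] - want[first])) < 1e-4


@pytest.mark.parametrize("method", [1, 2, 3])
def test_conversions_produce_packed_integers(pack_ctx, method):
    """All three conversion methods turn a packed-matrix vector into one
    constant ciphertext per component."""
    ctx, layout = pack_ctx
    values = np.array([0.7, -0.4, 0.9])
    vec = place(np.repeat(values, layout.block), ctx.n_slots)
    # pre-rescale input scale: the conversions rotate, and rotations are
    # only clean when the following rescale divides the key-switch noise
    ct = ctx.encrypt(ctx.encode(vec, ctx.chain.L, DELTA * DELTA))
    fn = {1: convert_method1, 2: convert_method2, 3: convert_method3}[method]
    outs = fn(ctx, ct, layout, DELTA)
    assert len(outs) == layout.N
    for want, out in zip(values, outs):
        got = np.real(ctx.decrypt_vector(out))
        assert np.max(np.abs(got - want)) < 1e-3, f"method {method}"


def test_required_rotations_cover_actual_use(pack_ctx):
    """The advertised rotation-key requirement sets are sufficient: the
    conversions above ran with exactly those keys."""
    ctx, layout = pack_ctx
    for m in (1, 2, 3):
        need = required_rotations_convert(m, ctx.n_slots, layout)
        assert need <= set(ctx.keys.rot_keys)
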