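"""Plaintext slot layouts and homomorphic encoding conversions.

Two encodings are used by the pipeline:

* *packed-matrix* encoding puts an N x k matrix (and the derived vectors)
  into one ciphertext, k^2 slots per individual: the matrix with each row
  cloned k times, its transpose with each element cloned k times, and
  vectors with each entry cloned k^2 times.  Matrix products then reduce to
  SIMD products plus log-depth rotation trees (SumRowVec / SumColVec /
  cyclic folds).

* *packed-integer* encoding holds a single value cloned into every slot.
  Products of packed-integer ciphertexts with SIMD row vectors need no
  rotations at all, which is what makes the SNP phase cheap.

Three conversion methods turn one packed-matrix ciphertext into N
packed-integer ciphertexts; they trade rotations against bit-mask
multiplications and depth.  All mask multiplications consume one level, the
same as a homomorphic multiplication (a known inefficiency, kept for
fidelity to the operation counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .ckks import Ciphertext, CkksContext


# ---------------------------------------------------------------------------
# Layouts (plaintext side)
# ---------------------------------------------------------------------------

VALID_KINDS = ("row-clone", "element-row-clone", "col-clone",
               "integer-clone", "simd")


def _next_pow2(x: int) -> int:
    return 1 << max(0, (int(x) - 1).bit_length())


@dataclass(frozen=True)
class MatrixLayout:
    """Metadata for a packed layout: N individuals, k columns, n/2 slots."""

    kind: str
    N: int
    k: int
    n_slots: int

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown layout kind {self.kind!r}")
        if self.N < 1 or self.k < 1:
            raise ValueError("N and k must be positive")

    @property
    def Nbar(self) -> int:
        return _next_pow2(self.N)

    @property
    def block(self) -> int:
        return self.k * self.k

    @property
    def slots_used(self) -> int:
        if self.kind in ("integer-clone", "simd"):
            return self.n_slots
        return self.N * self.block

    @property
    def n_ciphertexts(self) -> int:
        """Row-block split count when one ciphertext does not suffice."""
        if self.kind in ("integer-clone", "simd"):
            return 1
        per_ct = self.n_slots // self.block
        if per_ct == 0:
            raise ValueError("k^2 exceeds the slot count")
        return -(-self.N // per_ct)


def _check_capacity(layout: MatrixLayout) -> None:
    if layout.Nbar * layout.block > layout.n_slots:
        raise ValueError(
            f"padded layout needs {layout.Nbar * layout.block} slots, "
            f"only {layout.n_slots} available")


def pack_matrix(X: np.ndarray) -> np.ndarray:
    """Row-major with each row repeated k times: [[1,2],[3,4]] -> 12123434."""
    X = np.asarray(X, dtype=np.float64)
    N, k = X.shape
    return np.repeat(X[:, None, :], k, axis=1).reshape(N * k * k)


def unpack_matrix(vec: np.ndarray, N: int, k: int) -> np.ndarray:
    return np.asarray(vec, dtype=np.float64)[: N * k * k] \
        .reshape(N, k, k)[:, 0, :].copy()


def pack_transpose(X: np.ndarray) -> np.ndarray:
    """Element-major with each element repeated k times: -> 11223344."""
    X = np.asarray(X, dtype=np.float64)
    N, k = X.shape
    return np.repeat(X.reshape(N * k), k)


def unpack_transpose(vec: np.ndarray, N: int, k: int) -> np.ndarray:
    return np.asarray(vec, dtype=np.float64)[: N * k * k] \
        .reshape(N, k, k)[:, :, 0].copy()


def pack_vector_colclone(y: np.ndarray, k: int) -> np.ndarray:
    """Each entry repeated k^2 times: [5,6], k=2 -> [5,5,5,5,6,6,6,6]."""
    y = np.asarray(y, dtype=np.float64).ravel()
    return np.repeat(y, k * k)


def unpack_vector_colclone(vec: np.ndarray, N: int, k: int) -> np.ndarray:
    return np.asarray(vec, dtype=np.float64)[: N * k * k] \
        .reshape(N, k * k)[:, 0].copy()


def place(vec: np.ndarray, n_slots: int) -> np.ndarray:
    """Zero-pad a packed vector to the full slot count."""
    vec = np.asarray(vec, dtype=np.float64)
    if len(vec) > n_slots:
        raise ValueError("packed vector exceeds slot capacity")
    out = np.zeros(n_slots)
    out[: len(vec)] = vec
    return out


def split_row_blocks(X: np.ndarray, layout: MatrixLayout) -> list:
    """Multi-ciphertext fallback: split rows into blocks that fit one
    ciphertext each (plaintext-side only)."""
    per_ct = layout.n_slots // layout.block
    N = X.shape[0]
    return [X[i: i + per_ct] for i in range(0, N, per_ct)]


# ---------------------------------------------------------------------------
# Rotation-based reductions
# ---------------------------------------------------------------------------

def fold_sum(ctx: CkksContext, ct: Ciphertext, stride: int,
             reps: Optional[int] = None) -> Ciphertext:
    """Rotate-and-add doubling tree summing slots with the given stride.

    With ``reps`` = n_slots/stride (the default) this is the full cyclic
    fold: every slot receives the sum of its congruence class mod stride,
    so with one value per individual at stride spacing (zeros elsewhere)
    the total is replicated everywhere.  ``reps`` must be a power of two.
    """
    reps = ctx.n_slots // stride if reps is None else reps
    if reps & (reps - 1):
        raise ValueError("fold repetition count must be a power of two")
    out = ct
    off = stride
    while off < stride * reps:
        out = ctx.add(out, ctx.rotate(out, off))
        off *= 2
    return out


def fill_clone(ctx: CkksContext, ct: Ciphertext, used: int) -> Ciphertext:
    """Clone the first ``used`` slots (rest must be zero) to fill all slots.

    log2(n_slots/used) rotations; ``used`` must divide n_slots evenly by a
    power of two.
    """
    span = ctx.n_slots // used
    if span * used != ctx.n_slots or span & (span - 1):
        raise ValueError("used slot count must divide n/2 by a power of two")
    out = ct
    off = used
    while off < ctx.n_slots:
        out = ctx.add(out, ctx.rotate(out, -off))
        off *= 2
    return out


def sum_row_vec(ctx: CkksContext, ct: Ciphertext,
                layout: MatrixLayout) -> Ciphertext:
    """Sum each length-k row segment (ceil(log k) rotations, no mask).

    Valid at the first slot of every row segment; the other slots carry
    wrap-around garbage unless the layout is k-periodic inside each block
    (as row-clone layouts are), in which case the sum is replicated.
    """
    out = ct
    off = 1
    while off < layout.k:
        out = ctx.add(out, ctx.rotate(out, off))
        off *= 2
    return out


def sum_col_vec(ctx: CkksContext, ct: Ciphertext, layout: MatrixLayout,
                mask_scale: Fraction) -> Ciphertext:
    """Sum the k row segments of each block (stride-k rotations) and apply
    one bit mask keeping the first row segment of every block."""
    out = ct
    off = layout.k
    while off < layout.block:
        out = ctx.add(out, ctx.rotate(out, off))
        off *= 2
    mask = np.zeros(ctx.n_slots)
    idx = np.arange(ctx.n_slots)
    mask[(idx % layout.block) < layout.k] = 1.0
    return ctx.cmult_raw(out, mask, mask_scale, is_mask=True)


# ---------------------------------------------------------------------------
# Encoding conversions: packed-matrix vector -> N packed-integer ciphertexts
# ---------------------------------------------------------------------------

def _conversion_geometry(ctx: CkksContext, layout: MatrixLayout):
    _check_capacity(layout)
    s = layout.block          # slots per component
    Nbar = layout.Nbar
    period = Nbar * s         # pattern period after padding
    return s, Nbar, period


def _component_mask(ctx: CkksContext, comp: int, s: int,
                    period: int) -> np.ndarray:
    idx = np.arange(ctx.n_slots)
    return (((idx % period) // s) == comp).astype(np.float64)


def convert_method1(ctx: CkksContext, ct: Ciphertext, layout: MatrixLayout,
                    mask_scale: Fraction, filled: bool = False) -> list:
    """Fill-clone, one mask per component, then per-ciphertext cloning.

    Costs log2(n/(2 Nbar k^2)) + N*log2(Nbar) rotations and N mask
    multiplications; depth cost one mask level.  Output i decodes to the
    constant y_i in every slot.  ``filled`` skips stage 1 when the input is
    already periodic over all slots.
    """
    s, Nbar, period = _conversion_geometry(ctx, layout)
    if not filled:
        ct = fill_clone(ctx, ct, period)
    outs = []
    for c in range(layout.N):
        masked = ctx.cmult_raw(
            ct, _component_mask(ctx, c, s, period), mask_scale, is_mask=True)
        out = masked
        off = s
        while off < period:
            out = ctx.add(out, ctx.rotate(out, off))
            off *= 2
        outs.append(out)
    return outs


def convert_method2(ctx: CkksContext, ct: Ciphertext, layout: MatrixLayout,
                    mask_scale: Fraction, filled: bool = False) -> list:
    """Binary-tree conversion: Nbar rotations, 4*Nbar mask multiplications,
    2*Nbar additions, and a ceil(log N) depth increase (one mask level per
    tree level, each followed by a rescale)."""
    s, Nbar, period = _conversion_geometry(ctx, layout)
    if not filled:
        ct = fill_clone(ctx, ct, period)
    idx = np.arange(ctx.n_slots)
    # each node carries a phase: the slot offset where its cloned runs start
    # (the second combination of each split is misaligned by half a period)
    nodes = [(ct, 0)]
    # plaintext simulation of the same schedule tracks which component ends
    # up in which leaf (slot values = component indices)
    sim = ((idx % period) // s).astype(np.float64)
    sims = [sim]
    half = s
    while half < period:
        new_nodes, new_sims = [], []
        for (node, phase), nsim in zip(nodes, sims):
            def M(psi):
                return (((idx - psi) % (2 * half)) < half).astype(np.float64)
            m0, m1 = M(phase), M(phase + half)
            rot = ctx.rotate(node, -half)
            a1 = ctx.cmult_raw(node, m0, mask_scale, is_mask=True)
            a2 = ctx.cmult_raw(rot, m1, mask_scale, is_mask=True)
            b1 = ctx.cmult_raw(node, m1, mask_scale, is_mask=True)
            b2 = ctx.cmult_raw(rot, m0, mask_scale, is_mask=True)
            new_nodes.append((ctx.rescale(ctx.add(a1, a2)), phase))
            new_nodes.append((ctx.rescale(ctx.add(b1, b2)),
                              (phase + half) % period))
            rsim = np.roll(nsim, half)
            new_sims.extend([nsim * m0 + rsim * m1,
                             nsim * m1 + rsim * m0])
        nodes, sims = new_nodes, new_sims
        half *= 2
    by_component = {}
    for (node, _), nsim in zip(nodes, sims):
        comp = int(round(nsim[0]))
        if not np.allclose(nsim, comp):
            raise AssertionError("binary-tree leaf is not a pure component")
        by_component[comp] = node
    return [by_component[c] for c in range(layout.N)]


def convert_method3(ctx: CkksContext, ct: Ciphertext, layout: MatrixLayout,
                    mask_scale: Fraction, filled: bool = False) -> list:
    """Hoisted-rotation conversion: Nbar-1 rotations sharing one CRT
    decomposition, then Nbar^2 mask multiplications and Nbar*(Nbar-1)
    additions; depth cost one mask level."""
    s, Nbar, period = _conversion_geometry(ctx, layout)
    if not filled:
        ct = fill_clone(ctx, ct, period)
    rots = [ct]
    if Nbar > 1:
        comps = ctx.hoist_decompose(ct)
        for m in range(1, Nbar):
            rots.append(ctx.hoisted_rotate(ct, comps, -m * s))
    outs = []
    for c in range(layout.N):
        acc = None
        for m, rct in enumerate(rots):
            # rotation by -m*s moved component c to blocks == c+m (mod Nbar)
            mask = _component_mask(ctx, (c + m) % Nbar, s, period)
            term = ctx.cmult_raw(rct, mask, mask_scale, is_mask=True)
            acc = term if acc is None else ctx.add(acc, term)
        outs.append(acc)
    return outs


# ---------------------------------------------------------------------------
# Rotation-key requirements
# ---------------------------------------------------------------------------

def _doubling_offsets(start: int, stop: int) -> list:
    out = []
    off = start
    while off < stop:
        out.append(off)
        off *= 2
    return out


def required_rotations_fold(n_slots: int, stride: int,
                            reps: Optional[int] = None) -> set:
    reps = n_slots // stride if reps is None else reps
    return set(_doubling_offsets(stride, stride * reps))


def required_rotations_fill(n_slots: int, used: int) -> set:
    return {-o for o in _doubling_offsets(used, n_slots)}


def required_rotations_sum_row(k: int) -> set:
    return set(_doubling_offsets(1, k))


def required_rotations_sum_col(k: int) -> set:
    return set(_doubling_offsets(k, k * k))


def required_rotations_convert(method: int, ctx_slots: int,
                               layout: MatrixLayout) -> set:
    s = layout.block
    period = layout.Nbar * s
    fill = {-o for o in _doubling_offsets(period, ctx_slots)}
    if method == 1:
        return fill | set(_doubling_offsets(s, period))
    if method == 2:
        return fill | {-o for o in _doubling_offsets(s, period)}
    if method == 3:
        return fill | {-m * s for m in range(1, layout.Nbar)}
    raise ValueError("method must be 1, 2 or 3")
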