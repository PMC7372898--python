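"""Encrypted semi-parallel GWAS pipeline over the RNS CKKS scheme.

The circuit evaluates the division-free semi-parallel score from
:mod:`hegwas.gwas_plain` on encrypted inputs.  The covariate phase works in
the packed-matrix encoding (one slot block of k^2 per individual): a closed
form for the gradient step yields rho, W = rho(1-rho) and the degree-8
polynomial surrogate zeta; the k x k information matrix H is folded into one
block, its k^2 entries are extracted with hoisted rotations and bit masks,
and the adjoint/determinant are assembled from shared 2x2 minors with lazy
relinearization.  W, W*zeta_star and the adjoint are then converted to the
packed-integer encoding (one constant per ciphertext), after which the
SNP-dependent phase S* = detH*S - X_1(B_1(X_1^T(W_1 S))) and the score
numerators/denominators use only SIMD products and binary-tree additions:
zero rotations and exactly k^2 relinearizations (the products with B_1).

Two policies shape the circuit:

* every rotation and relinearization is applied at a pre-rescale scale
  (>= Delta^2), so the additive key-switch noise of the single-digit CRT
  decomposition is divided down by the following rescale;
* levels are planned from the end of the circuit: each input is encrypted
  with 1 + (its remaining multiplicative depth) CRT limbs, and operand
  scales are aligned explicitly (no silent alignment).

The client keeps the secret key: decryption, the division by the
determinant and the square root happen in :func:`client_finalize`.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Optional

import numpy as np

from .ckks import (Ciphertext, CkksContext, NoiseParams, sizeof_ciphertext,
                   sizeof_secret_key, sizeof_switchkey)
from .gwas_plain import DEFAULT_ALPHA, SIGMOID_SLOPE, GwasDataset, p_values
from .packing import (MatrixLayout, _doubling_offsets, convert_method1,
                      convert_method2, convert_method3, fold_sum,
                      pack_matrix, pack_transpose, pack_vector_colclone,
                      place, required_rotations_convert,
                      required_rotations_fold)
from .rns import generate_modulus_chain, poly_add, poly_neg

# Evaluation profiles.  The toy profile carries no lattice security; it is
# sized so the full circuit (22 levels for conversion methods 1/3, 24 for
# method 2) fits with headroom for tests.  The full profile is the
# storage/planning profile; it is never evaluated end to end here.
TOY_PROFILE = {"n": 1 << 12, "p": 45, "L": 22}
FULL_PROFILE = {"n": 1 << 15, "p": 50, "L": 17}

# Multiplicative depth of the SNP-dependent phase, counted from the first
# use of the encrypted SNP matrix: W1*S, X1^T(.), B1(.), X1(.), then the
# numerator product and the denominator's S*^2 * w.
SNP_MULT_DEPTH = 6
# X1 enters one product later (its first use multiplies W1*S).
X1_MULT_DEPTH = 5
# Levels consumed before the SNP operands are prepared (toy circuit).
MIN_TOY_LEVELS = 22

# Public protocol constant: the adjoint/determinant (and w*zeta_star, which
# is proportional to the determinant) are divided by this fixed normalizer
# when the SNP-phase operands are prepared, so the values of S*, the score
# numerators and denominators stay small while their scales stay near
# Delta -- maximizing signal-to-noise without overflowing the last
# coefficient moduli.  The two factors cancel in z = num/(det sqrt(den));
# the client multiplies the reported raw quantities back up.
DET_NORMALIZER = 512.0


# ---------------------------------------------------------------------------
# Level planning
# ---------------------------------------------------------------------------

@dataclass
class LevelPlan:
    """Per-input first-use levels and the rotation-key schedule.

    ``input_levels`` maps input names to the number of CRT limbs they are
    encrypted with (= 1 + remaining multiplicative depth).  For the full
    profile the rotation-key schedule records at which level groups of keys
    are held once the circuit has descended past their last use, with the
    number of keys per level.
    """

    profile: str
    L: int
    scale_bits: int
    input_levels: dict
    rotation_keys: dict
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "profile": self.profile,
            "L": self.L,
            "scale_bits": self.scale_bits,
            "input_levels": dict(self.input_levels),
            "rotation_keys": {str(k): v for k, v in self.rotation_keys.items()},
            "notes": dict(self.notes),
        }


def plan_levels(chain, N: int, k: int, profile: str = "toy",
                rotation_offsets=None) -> LevelPlan:
    """Assign first-use levels to every encrypted input.

    Limb counts are derived by counting multiplicative depth from the END
    of the circuit: the SNP matrix S supports depth ``SNP_MULT_DEPTH`` (= 6)
    of remaining computation, so it is encrypted with 7 limbs instead of L;
    the packed-integer covariates X1 enter one product later (6 limbs).
    The covariate-phase inputs (X, X^T, y) are used immediately and carry
    all L limbs.
    """
    if k != 4:
        raise ValueError("the level plan is fixed for k = 4 covariates")
    if profile == "paper":
        if chain.L != FULL_PROFILE["L"]:
            raise ValueError("the paper profile requires an L=17 chain")
        return LevelPlan(
            profile="paper",
            L=chain.L,
            scale_bits=chain.p,
            input_levels={"X": chain.L, "Xt": chain.L, "y": chain.L,
                          "S": SNP_MULT_DEPTH + 1, "X1": X1_MULT_DEPTH + 1},
            rotation_keys={17: 16, 12: 13, 9: 12},
            notes={
                "S": "remaining depth 6 from its first use -> 7 limbs",
                "X1": "remaining depth 5 from its first use -> 6 limbs",
                "rotation_keys": "keys compressed to the working level as "
                                 "the circuit descends: 16 at 17 limbs, 13 "
                                 "at 12, 12 at 9",
            })
    if profile != "toy":
        raise ValueError(f"unknown profile {profile!r}")
    if chain.L < MIN_TOY_LEVELS:
        raise ValueError(
            f"circuit depth exceeds L-1: the toy circuit needs at least "
            f"{MIN_TOY_LEVELS} limbs, chain has {chain.L}")
    offsets = sorted(rotation_offsets) if rotation_offsets else []
    return LevelPlan(
        profile="toy",
        L=chain.L,
        scale_bits=chain.p,
        input_levels={"X": chain.L, "Xt": chain.L, "y": chain.L,
                      "S": SNP_MULT_DEPTH + 1, "X1": X1_MULT_DEPTH + 1},
        rotation_keys={chain.L: len(offsets)},
        notes={"rotation_offsets": ",".join(str(o) for o in offsets)},
    )


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class EncryptedInputs:
    X: Ciphertext                 # packed-matrix (row-clone)
    Xt: Ciphertext                # packed-transpose (element-row-clone)
    y: Ciphertext                 # column-clone vector
    X1: list                      # N lists of k packed-integer ciphertexts
    S: list                       # N SIMD ciphertexts, slots indexed by SNP
    bytes_by_input: dict = field(default_factory=dict)


@dataclass
class RhoWZeta:
    rho: Ciphertext
    d: Ciphertext                 # rho - 1/2 (column-clone)
    W: Ciphertext                 # rho(1-rho)
    zeta: Ciphertext


@dataclass
class AdjDet:
    components: dict              # (a, b) -> packed-integer H[a, b]
    B1: dict                      # (i, j) -> packed-integer adj(H)[i, j]
    det: Ciphertext               # packed-integer determinant
    B: Ciphertext                 # packed-matrix adjoint, slot(a,b)=adj[b,a]


@dataclass
class ConvertedOperands:
    W1: list                      # N packed-integer weights, SNP-phase scale
    wz1: list                     # N packed-integer (w * zeta_star) values
    w_den: list                   # N packed-integer weights, denominator scale
    B1: dict
    method: int


@dataclass
class GwasEncryptedResult:
    z: np.ndarray
    p: np.ndarray
    numerators: np.ndarray
    denominators: np.ndarray
    detH: float
    degenerate: np.ndarray
    scale_factors: dict
    ids: Optional[list] = None


@dataclass
class RunOutput:
    result: GwasEncryptedResult
    manifest: dict


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class EncryptedPipeline:
    """Server-side evaluator for one cohort geometry (N individuals, k = 4
    covariate columns, M SNPs) on a given CKKS context."""

    def __init__(self, ctx: CkksContext, N: int, M: int, k: int = 4,
                 conversion_method: int = 1, alpha: float = DEFAULT_ALPHA):
        if k != 4:
            raise ValueError("the encrypted Cramer inversion is fixed at k=4")
        if conversion_method not in (1, 2, 3):
            raise ValueError("conversion method must be 1, 2 or 3")
        self.ctx = ctx
        self.N, self.M, self.k = N, M, k
        self.block = k * k
        self.layout = MatrixLayout("col-clone", N, k, ctx.n_slots)
        if self.layout.Nbar * self.block > ctx.n_slots:
            raise ValueError("N k^2 exceeds the slot capacity")
        if M > ctx.n_slots:
            raise ValueError("M exceeds the slot capacity of one ciphertext")
        self.method = conversion_method
        self.alpha = alpha
        self.used = N * self.block
        self.delta = Fraction(2) ** ctx.chain.p
        idx = np.arange(ctx.n_slots)
        self._idx = idx
        self._ones = np.ones(self.used)
        in_use = (idx < self.used).astype(np.float64)
        self._mask_first_run = ((idx % self.block) < k).astype(np.float64)
        self._mask_first_run_used = self._mask_first_run * in_use
        self._mask_b0 = (idx % k == 0).astype(np.float64)

    # -- small helpers ------------------------------------------------------

    @property
    def _p(self) -> int:
        return self.ctx.chain.p

    def _scale_targets(self) -> dict:
        p = self._p
        return {"W1": Fraction(2) ** p,
                "wz1": Fraction(2) ** p,
                "w_den": Fraction(2) ** (p - 12)}

    def _comp_mask(self, c: int) -> np.ndarray:
        return (self._idx % self.block == c).astype(np.float64)

    def _neg(self, ct: Ciphertext) -> Ciphertext:
        return Ciphertext([poly_neg(p) for p in ct.polys], ct.level,
                          ct.scale, ct.tag)

    def _pt_minus_ct(self, vec, ct: Ciphertext) -> Ciphertext:
        """plaintext(vec) - ct, with the plaintext encoded at ct's scale."""
        pt = self.ctx.encode(vec, ct.level, ct.scale)
        out = self._neg(ct)
        out.polys[0] = poly_add(out.polys[0], pt.poly)
        return out

    def _tree_sum(self, cts: list) -> Ciphertext:
        """Binary-tree addition (order-independent, log-depth noise)."""
        work = list(cts)
        if not work:
            raise ValueError("empty sum")
        while len(work) > 1:
            nxt = [self.ctx.add(work[i], work[i + 1])
                   for i in range(0, len(work) - 1, 2)]
            if len(work) % 2:
                nxt.append(work[-1])
            work = nxt
        return work[0]

    def _sum_stride(self, ct: Ciphertext, start: int, stop: int) -> Ciphertext:
        out = ct
        off = start
        while off < stop:
            out = self.ctx.add(out, self.ctx.rotate(out, off))
            off *= 2
        return out

    def _fill_neg(self, ct: Ciphertext, start: int, stop: int) -> Ciphertext:
        out = ct
        off = start
        while off < stop:
            out = self.ctx.add(out, self.ctx.rotate(out, -off))
            off *= 2
        return out

    def _cmul_const(self, ct: Ciphertext, c: float) -> Ciphertext:
        return self.ctx.cmult_raw(ct, c * self._ones, self.delta)

    def _mult_align(self, a: Ciphertext, b: Ciphertext,
                    relin: bool = True) -> Ciphertext:
        lv = min(a.level, b.level)
        out = self.ctx.mult(self.ctx.drop_to_level(a, lv),
                            self.ctx.drop_to_level(b, lv))
        return self.ctx.relinearize(out) if relin else out

    def _align(self, cts: list) -> list:
        """Bring ciphertexts to a common (level, scale) explicitly.

        Equal scales only need limb drops; otherwise one constant
        multiplication + rescale per ciphertext lands everything on the
        exact target scale (max scale carried at ~2^p constant accuracy).
        """
        ctx = self.ctx
        lv = min(ct.level for ct in cts)
        scales = {ct.scale for ct in cts}
        if len(scales) == 1:
            return [ctx.drop_to_level(ct, lv) for ct in cts]
        lv -= 1
        q = ctx.chain.primes[lv]
        target = max(scales) * (Fraction(2) ** self._p) / q
        return [ctx.level_reduce(ct, lv, target) for ct in cts]

    def _settle(self, ct: Ciphertext, level: int, scale: Fraction,
                factor: float = 1.0) -> Ciphertext:
        """Land a ciphertext on an exact (level, scale) target, optionally
        multiplying its values by a public constant ``factor``.

        One constant multiplication at the current level makes the scale
        telescope exactly to ``scale`` through the following rescales:
        const = scale * prod(q_level..q_{ct.level-1}) / ct.scale.  The
        caller must leave enough limbs that factor*const stays well above
        one (otherwise the constant's encoding would destroy precision);
        :meth:`_convert_raw` plans for this.
        """
        ctx = self.ctx
        if ct.scale == scale and factor == 1.0:
            return ctx.drop_to_level(ct, level)
        if ct.level <= level:
            raise ValueError("cannot settle without a spare level")
        const = scale / ct.scale
        for j in range(level, ct.level):
            const *= ctx.chain.primes[j]
        if const * Fraction(factor) < 1:
            raise ValueError("settle constant below one: plan more limbs")
        work = ctx.cmult(ct, ctx.encode(factor, ct.level, const))
        for _ in range(ct.level - level):
            work = ctx.rescale(work)
        assert work.level == level and work.scale == scale
        return work

    # -- key requirements ---------------------------------------------------

    def required_rotation_keys(self) -> set:
        ns = self.ctx.n_slots
        keys = set(required_rotations_fold(ns, self.block))
        keys |= set(_doubling_offsets(1, self.k))
        keys |= set(_doubling_offsets(self.k, self.block))
        keys |= {-o for o in _doubling_offsets(1, self.k)}
        keys |= {-o for o in _doubling_offsets(self.k, self.block)}
        keys |= set(range(1, self.block))          # hoisted H extraction
        keys |= required_rotations_convert(self.method, ns, self.layout)
        keys.discard(0)
        return keys

    def rotation_key_levels(self) -> dict:
        """Maximum use level per rotation offset, so switch keys can be
        generated with only the limbs they will ever need."""
        L = self.ctx.chain.L
        ns = self.ctx.n_slots
        levels: dict = {}

        def need(off: int, level: int) -> None:
            if off:
                levels[off] = max(levels.get(off, 0), level)

        for off in required_rotations_fold(ns, self.block):
            need(off, L)                      # covariate fold at the top
        for off in _doubling_offsets(self.k, self.block):
            need(off, L - 1)                  # run sums/fills, pre-rescale
            need(-off, L - 1)
        for off in range(1, self.block):
            need(off, L - 4)                  # hoisted H extraction
        for off in _doubling_offsets(1, self.k):
            need(off, L - 4)
            need(-off, L - 12)                # SNP-slot fill, deep in chain
        for off in required_rotations_convert(self.method, ns, self.layout):
            need(off, L - 4)                  # conversions start below W
        return levels

    def relin_key_levels(self) -> dict:
        """Maximum use level per relinearization power: the 4-poly H product
        settles one limb below the weights, quintic SNP products are confined
        to the terminal limbs."""
        L = self.ctx.chain.L
        return {2: L, 3: L - 4, 4: 5}

    # -- encryption ---------------------------------------------------------

    def encrypt_inputs(self, ds: GwasDataset, plan: LevelPlan
                       ) -> EncryptedInputs:
        ctx = self.ctx
        ns = ctx.n_slots
        lv = plan.input_levels
        X = ctx.encrypt_vector(place(pack_matrix(ds.X), ns), lv["X"],
                               tag="packed-matrix")
        Xt = ctx.encrypt_vector(place(pack_transpose(ds.X), ns), lv["Xt"],
                                tag="packed-transpose")
        y = ctx.encrypt_vector(place(pack_vector_colclone(ds.y, self.k), ns),
                               lv["y"], tag="column-clone")
        X1 = [[ctx.encrypt_vector(float(ds.X[i, a]), lv["X1"],
                                  tag="packed-integer")
               for a in range(self.k)] for i in range(self.N)]
        S = [ctx.encrypt_vector(ds.S[i, :], lv["S"], tag="simd-vector")
             for i in range(self.N)]
        chain = ctx.chain
        sizes = {
            "X": sizeof_ciphertext(lv["X"], chain),
            "Xt": sizeof_ciphertext(lv["Xt"], chain),
            "y": sizeof_ciphertext(lv["y"], chain),
            "X1": self.N * self.k * sizeof_ciphertext(lv["X1"], chain),
            "S": self.N * sizeof_ciphertext(lv["S"], chain),
        }
        return EncryptedInputs(X, Xt, y, X1, S, sizes)

    # -- Algorithm steps 1-5: rho, W, zeta ----------------------------------

    def eval_rho_w_zeta(self, enc: EncryptedInputs) -> RhoWZeta:
        ctx = self.ctx
        # one closed-form gradient step: d = slope*alpha * X X^T (y - 1/2)
        t1 = ctx.cadd(enc.y, -0.5 * self._ones)
        p1 = ctx.relinearize(ctx.mult(enc.Xt, t1))
        v1 = ctx.rescale(fold_sum(ctx, p1, self.block))
        p2 = ctx.relinearize(ctx.mult(
            ctx.drop_to_level(enc.Xt, v1.level), v1))
        p2 = self._sum_stride(p2, self.k, self.block)
        cmask = SIGMOID_SLOPE * self.alpha * self._mask_first_run_used
        p2 = ctx.cmult_raw(p2, cmask, self.delta, is_mask=True)
        p2 = self._fill_neg(p2, self.k, self.block)
        d = ctx.rescale(ctx.rescale(p2))
        rho = ctx.cadd(d, 0.5 * self._ones)
        # W = rho(1-rho) = 1/4 - d^2
        d2 = ctx.rescale(ctx.relinearize(ctx.mult(d, d)))
        W = self._pt_minus_ct(0.25 * self._ones, d2)
        # zeta via binary-tree powers of d
        d4 = ctx.rescale(ctx.relinearize(ctx.mult(d2, d2)))
        d8 = ctx.rescale(ctx.relinearize(ctx.mult(d4, d4)))
        d6 = ctx.rescale(ctx.relinearize(ctx.mult(
            ctx.drop_to_level(d2, d4.level), d4)))
        pows = {2: d2, 4: d4, 6: d6, 8: d8}
        even_const = {2: -8.0, 4: -32.0, 6: -128.0, 8: -512.0}
        even_y = {2: 16.0, 4: 64.0, 6: 256.0, 8: 1024.0}
        odd_const = {2: -32.0 / 3.0, 4: -256.0 / 5.0, 6: -1536.0 / 7.0}
        raw = ([self._cmul_const(pows[t], even_const[t]) for t in (2, 4, 6, 8)]
               + [self._cmul_const(pows[t], even_y[t]) for t in (2, 4, 6, 8)]
               + [self._cmul_const(pows[t], odd_const[t]) for t in (2, 4, 6)])
        al = self._align(raw)
        C = ctx.cadd(self._tree_sum(al[0:4]), -2.0 * self._ones)
        G = ctx.cadd(self._tree_sum(al[4:8]), 4.0 * self._ones)
        O = self._tree_sum(al[8:11])
        Yg = ctx.relinearize(ctx.mult(ctx.drop_to_level(enc.y, G.level), G))
        dO = ctx.relinearize(ctx.mult(ctx.drop_to_level(d, O.level), O))
        zc = self._align([C, Yg, dO])
        zeta = ctx.rescale(ctx.add(ctx.add(zc[0], zc[1]), zc[2]))
        return RhoWZeta(rho=rho, d=d, W=W, zeta=zeta)

    # -- Algorithm steps 6-7: H, adjoint, determinant ------------------------

    def eval_H(self, enc: EncryptedInputs, W: Ciphertext) -> Ciphertext:
        """Packed H = X^T W X, folded so every k^2 block holds H[a, b]
        (left un-rescaled for the extraction rotations)."""
        ctx = self.ctx
        lv = W.level
        P = ctx.mult(ctx.drop_to_level(enc.Xt, lv), W)
        P = ctx.mult(P, ctx.drop_to_level(enc.X, lv))
        P = ctx.relinearize(P)
        return fold_sum(ctx, P, self.block)

    def eval_H_adj_det(self, H: Ciphertext) -> AdjDet:
        """Extract the k^2 entries of H with hoisted rotations + masks and
        assemble adjoint/determinant from shared 2x2 minors.

        All multiplications stay unrelinearized until each component is
        complete; rescales are deferred until after the rotations.
        """
        ctx = self.ctx
        k, block, delta = self.k, self.block, self.delta
        comps = ctx.hoist_decompose(H)
        rots = [H] + [ctx.hoisted_rotate(H, comps, m)
                      for m in range(1, block)]
        mask_pt = [ctx.encode(self._comp_mask(j), H.level, delta)
                   for j in range(block)]
        comp_ct = {}
        for c in range(block):
            terms = [ctx.cmult(rots[m], mask_pt[(c - m) % block], is_mask=True)
                     for m in range(block)]
            hc = self._tree_sum(terms)
            hc = ctx.rescale(ctx.rescale(ctx.rescale(hc)))
            comp_ct[(c // k, c % k)] = hc
        # shared 2x2 minors m2[(r,s,c,d)] = H[r,c]H[s,d] - H[r,d]H[s,c]
        m2 = {}
        for (r, s) in combinations(range(k), 2):
            for (c, d) in combinations(range(k), 2):
                t1 = ctx.mult(comp_ct[(r, c)], comp_ct[(s, d)])
                t2 = ctx.mult(comp_ct[(r, d)], comp_ct[(s, c)])
                m2[(r, s, c, d)] = ctx.rescale(
                    ctx.relinearize(ctx.sub(t1, t2)))
        m2_level = next(iter(m2.values())).level

        def hd(r, c):
            return ctx.drop_to_level(comp_ct[(r, c)], m2_level)

        # determinant: Laplace along rows {0,1} x complementary minors
        dterms = []
        for (c, d) in combinations(range(k), 2):
            comp = tuple(sorted(set(range(k)) - {c, d}))
            t = ctx.mult(m2[(0, 1, c, d)], m2[(2, 3) + comp])
            if (c + d) % 2 == 0:      # sign (-1)^(c+d+1)
                t = self._neg(t)
            dterms.append(t)
        det = ctx.rescale(ctx.relinearize(self._tree_sum(dterms)))
        # adjoint components adj[i,j] = (-1)^(i+j) * minor(rows!=j, cols!=i)
        B1 = {}
        for i in range(k):
            for j in range(k):
                rows = tuple(r for r in range(k) if r != j)
                cols = tuple(c for c in range(k) if c != i)
                r0, r1, r2 = rows
                c0, c1, c2 = cols
                t0 = ctx.mult(hd(r0, c0), m2[(r1, r2, c1, c2)])
                t1 = ctx.mult(hd(r0, c1), m2[(r1, r2, c0, c2)])
                t2 = ctx.mult(hd(r0, c2), m2[(r1, r2, c0, c1)])
                cof = ctx.add(ctx.sub(t0, t1), t2)
                if (i + j) % 2:
                    cof = self._neg(cof)
                B1[(i, j)] = ctx.rescale(ctx.relinearize(cof))
        # packed-matrix adjoint with slot(a, b) = adj[b, a], the layout the
        # step-8 product against a row-index vector needs
        bterms = [ctx.cmult_raw(B1[(b, a)], self._comp_mask(a * k + b),
                                delta, is_mask=True)
                  for a in range(k) for b in range(k)]
        B = ctx.rescale(self._tree_sum(bterms))
        return AdjDet(components=comp_ct, B1=B1, det=det, B=B)

    # -- Algorithm step 8: zeta_star -----------------------------------------

    def eval_zeta_star(self, enc: EncryptedInputs, rwz: RhoWZeta,
                       adj: AdjDet) -> Ciphertext:
        """zeta_star = detH*zeta - X adj(H) X^T W zeta, evaluated as a chain
        of single ciphertexts (no intermediate may be N x N)."""
        ctx = self.ctx
        k, block, delta = self.k, self.block, self.delta
        u = ctx.rescale(self._mult_align(rwz.W, rwz.zeta))       # W zeta
        v = self._mult_align(enc.Xt, u)                          # X^T (.)
        v = ctx.rescale(fold_sum(ctx, v, block))
        t = self._mult_align(adj.B, v)                           # adj (.)
        t = self._sum_stride(t, k, block)
        t = ctx.cmult_raw(t, self._mask_first_run, delta, is_mask=True)
        t = self._fill_neg(t, k, block)
        t = ctx.rescale(ctx.rescale(t))
        q = self._mult_align(enc.X, t)                           # X (.)
        q = self._sum_stride(q, 1, k)
        q = ctx.cmult_raw(q, self._mask_b0, delta, is_mask=True)
        q = self._fill_neg(q, 1, k)
        q = ctx.rescale(ctx.rescale(q))
        dz = self._mult_align(adj.det, rwz.zeta)                 # detH*zeta
        dz = self._settle(dz, q.level, q.scale)
        return ctx.sub(dz, q)

    def mult_w_zeta_star(self, W: Ciphertext,
                         zeta_star: Ciphertext) -> Ciphertext:
        return self._mult_align(W, zeta_star)

    # -- encoding conversions -------------------------------------------------

    def _convert_raw(self, ct: Ciphertext, target_min: int,
                     target_scale: Fraction) -> list:
        import math
        ctx = self.ctx
        p = self._p
        boost = ct.scale < Fraction(2) ** (3 * p // 2)
        sigma = ct.scale * self.delta if boost else ct.scale
        if self.method == 2:
            internal = int(self.layout.Nbar - 1).bit_length()
            sigma_out_log = math.log2(float(sigma)) + 2.0
        else:
            internal = 0
            sigma_out_log = math.log2(float(sigma * self.delta))
        # leave enough limbs above the target that the settle constant is
        # comfortably above one (>= ~2^16 for an accurate encoding)
        hops = max(1, math.ceil(
            (sigma_out_log + 20.0 - math.log2(float(target_scale))) / p))
        need = target_min + internal + hops
        if ct.level < need:
            raise ValueError(
                f"conversion method {self.method} needs {need} limbs to "
                f"reach level {target_min}, operand has {ct.level} "
                f"(depth shortfall)")
        work = ctx.drop_to_level(ct, need)
        if boost:
            # boost to a pre-rescale scale so the conversion rotations do
            # not operate at the base scale
            work = ctx.cmult(work, ctx.encode(1.0, work.level, self.delta))
        fn = {1: convert_method1, 2: convert_method2,
              3: convert_method3}[self.method]
        return fn(ctx, work, self.layout, self.delta)

    def convert_inputs(self, W: Ciphertext, wz: Ciphertext,
                       B1: dict) -> ConvertedOperands:
        """Packed-matrix W and W*zeta_star -> N packed-integer ciphertexts
        each, settled at their SNP-phase levels and scales.  The adjoint is
        already available in packed-integer form and passes through."""
        t = self._scale_targets()
        s_level = SNP_MULT_DEPTH + 1
        w_raw = self._convert_raw(W, s_level, t["W1"])
        wz_raw = self._convert_raw(wz, 3, t["wz1"])
        W1 = [self._settle(c, s_level, t["W1"]) for c in w_raw]
        w_den = [self._settle(c, 3, t["w_den"]) for c in w_raw]
        # w*zeta_star is proportional to detH; divide the public normalizer
        # out so the numerator values stay bounded at full scale
        wz1 = [self._settle(c, 3, t["wz1"], factor=1.0 / DET_NORMALIZER)
               for c in wz_raw]
        return ConvertedOperands(W1=W1, wz1=wz1, w_den=w_den,
                                 B1=dict(B1), method=self.method)

    # -- Algorithm steps 9-11: SNP phase --------------------------------------

    def eval_s_star_and_z_parts(self, enc: EncryptedInputs,
                                conv: ConvertedOperands,
                                adj: AdjDet) -> tuple:
        """S* = detH*S - X1(B1(X1^T(W1 S))), then the per-SNP numerator
        sum_i (w zeta*)_i s*_i and denominator sum_i w_i s*_i^2.

        Everything is SIMD products and binary-tree additions: zero
        rotations, and exactly k^2 relinearizations (the B1 products);
        terminal rescales are skipped, the client divides by the exact
        scales after decryption.
        """
        ctx = self.ctx
        N, k = self.N, self.k
        q = ctx.chain.primes
        delta = self.delta
        t = self._scale_targets()
        s_level = SNP_MULT_DEPTH + 1
        # pre-phase operand preparation at the exact chain scales so every
        # addition in the phase matches without adjustment ciphertexts
        sT = t["W1"] * delta / q[s_level - 1]
        sr = delta * sT / q[s_level - 2]
        sc = delta * sr / q[s_level - 3]
        inv_norm = 1.0 / DET_NORMALIZER
        B1p = {key: self._settle(ct_, s_level - 2, delta, factor=inv_norm)
               for key, ct_ in conv.B1.items()}
        detp = self._settle(adj.det, s_level - 3, sc, factor=inv_norm)
        counters = ctx.counters
        counters.set_phase("SNP")
        T = [ctx.rescale(ctx.mult(conv.W1[i], enc.S[i])) for i in range(N)]
        r = [ctx.rescale(self._tree_sum(
            [ctx.mult(enc.X1[i][a], T[i]) for i in range(N)]))
            for a in range(k)]
        c = [ctx.rescale(self._tree_sum(
            [ctx.relinearize(ctx.mult(B1p[(b, a)], r[a])) for a in range(k)]))
            for b in range(k)]
        s_star = []
        for i in range(N):
            u = self._tree_sum([
                ctx.mult(ctx.drop_to_level(enc.X1[i][b], s_level - 3), c[b])
                for b in range(k)])
            dS = ctx.mult(detp, ctx.drop_to_level(enc.S[i], s_level - 3))
            s_star.append(ctx.rescale(ctx.sub(dS, u)))
        num = self._tree_sum([ctx.mult(conv.wz1[i], s_star[i])
                              for i in range(N)])
        den = self._tree_sum([ctx.mult(ctx.mult(s_star[i], s_star[i]),
                                       conv.w_den[i]) for i in range(N)])
        relins = counters.phase_total("SNP", "relinearizations")
        rotations = counters.phase_total("SNP", "rotations")
        if relins != k * k or rotations != 0:
            raise AssertionError(
                f"SNP-phase key-switch contract violated: "
                f"{relins} relinearizations, {rotations} rotations")
        return num, den


# ---------------------------------------------------------------------------
# Client finalization
# ---------------------------------------------------------------------------

def client_finalize(ctx: CkksContext, num: Ciphertext, den: Ciphertext,
                    det_ct: Ciphertext, M: int, ids=None,
                    degeneracy_tol: float = 1e-5) -> GwasEncryptedResult:
    """Decrypt the score parts and perform the deferred division and square
    root: z_j = num_j / (detH * sqrt(den_j)).  Non-positive (or relatively
    negligible) denominators flag the SNP as degenerate (p = 1)."""
    norm = DET_NORMALIZER
    num_v = norm * norm * np.asarray(ctx.decrypt_vector(num)[:M],
                                     dtype=np.float64)
    den_v = norm * norm * np.asarray(ctx.decrypt_vector(den)[:M],
                                     dtype=np.float64)
    det = float(np.median(ctx.decrypt_vector(det_ct)))
    factors = {"numerator_scale": str(num.scale),
               "denominator_scale": str(den.scale),
               "det_scale": str(det_ct.scale),
               "det_normalizer": str(norm)}
    if M == 0:
        empty = np.zeros(0)
        return GwasEncryptedResult(empty, empty, empty, empty, det,
                                   np.zeros(0, dtype=bool), factors,
                                   list(ids) if ids else [])
    ref = max(1.0, float(np.max(np.abs(den_v))))
    degenerate = den_v <= degeneracy_tol * ref
    z = np.zeros(M)
    good = ~degenerate
    z[good] = num_v[good] / (det * np.sqrt(den_v[good]))
    p = p_values(z)
    p[degenerate] = 1.0
    return GwasEncryptedResult(z=z, p=p, numerators=num_v,
                               denominators=den_v, detH=det,
                               degenerate=degenerate, scale_factors=factors,
                               ids=list(ids) if ids is not None else None)


# ---------------------------------------------------------------------------
# Orchestration and the run manifest
# ---------------------------------------------------------------------------

def build_manifest(ctx: CkksContext, pipe: EncryptedPipeline,
                   plan: LevelPlan, enc: EncryptedInputs,
                   result: GwasEncryptedResult, rotation_offsets,
                   elapsed: float) -> dict:
    chain = ctx.chain
    counters = ctx.counters
    snp_relins = counters.phase_total("SNP", "relinearizations")
    snp_rot = counters.phase_total("SNP", "rotations")
    sizes = dict(enc.bytes_by_input)
    sizes["secret_key"] = sizeof_secret_key(chain)
    sizes["rotation_keys"] = len(rotation_offsets) * sizeof_switchkey(
        chain.L, chain)
    return {
        "dims": {"N": pipe.N, "M": pipe.M, "k": pipe.k},
        "chain": {"n": chain.n, "p": chain.p, "L": chain.L,
                  "eps": chain.eps},
        "plan": plan.to_dict(),
        "conversion_method": pipe.method,
        "counters": counters.snapshot(),
        "snp_phase": {"relinearizations": snp_relins,
                      "rotations": snp_rot,
                      "key_switches": snp_relins + snp_rot},
        "sizes_bytes": sizes,
        "scale_factors": dict(result.scale_factors),
        "elapsed_seconds": elapsed,
    }


def save_manifest(path: str, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def prepare_context(N: int, M: int, k: int = 4, n: Optional[int] = None,
                    p: Optional[int] = None, L: Optional[int] = None,
                    seed: int = 0, conversion_method: int = 1,
                    sigma: float = 3.19) -> CkksContext:
    """Build a toy-profile context with all keys a cohort of this shape needs.

    Key material depends only on the cohort shape (N, k) and the conversion
    method, never on the data, so one prepared context can serve many
    datasets via ``run_encrypted(..., context=...)``.
    """
    prof = dict(TOY_PROFILE)
    if n is not None:
        prof["n"] = n
    if p is not None:
        prof["p"] = p
    if L is not None:
        prof["L"] = L
    chain = generate_modulus_chain(prof["p"], prof["n"], prof["L"])
    ctx = CkksContext(chain, NoiseParams(sigma=sigma), seed=seed)
    pipe = EncryptedPipeline(ctx, N, M, k,
                             conversion_method=conversion_method)
    ctx.keygen(rotation_indices=sorted(pipe.required_rotation_keys()),
               relin_powers=(2, 3, 4),
               rotation_levels=pipe.rotation_key_levels(),
               relin_levels=pipe.relin_key_levels())
    return ctx


def run_encrypted(ds: GwasDataset, n: Optional[int] = None,
                  p: Optional[int] = None, L: Optional[int] = None,
                  seed: int = 0, conversion_method: int = 1,
                  sigma: float = 3.19,
                  alpha: float = DEFAULT_ALPHA,
                  context: Optional[CkksContext] = None) -> RunOutput:
    """End-to-end encrypted run on a toy-profile chain.

    Builds the chain and keys (or reuses a ``prepare_context`` result),
    encrypts the cohort at its planned levels, evaluates the full circuit
    and finalizes client-side.  Returns the result together with the
    machine-readable run manifest (level plan, operation counters, sizes,
    scale factors).
    """
    start = time.time()
    if context is None:
        ctx = prepare_context(ds.N, ds.M, ds.k, n=n, p=p, L=L, seed=seed,
                              conversion_method=conversion_method,
                              sigma=sigma)
    else:
        ctx = context
        if ctx.keys is None:
            raise ValueError("provided context has no keys; run keygen first")
        ctx.counters.reset()
    chain = ctx.chain
    pipe = EncryptedPipeline(ctx, ds.N, ds.M, ds.k,
                             conversion_method=conversion_method, alpha=alpha)
    offsets = sorted(pipe.required_rotation_keys())
    missing = [o for o in offsets if o not in ctx.keys.rot_keys]
    if missing:
        raise ValueError(f"context lacks rotation keys for offsets {missing}")
    plan = plan_levels(chain, ds.N, ds.k, "toy", rotation_offsets=offsets)
    enc = pipe.encrypt_inputs(ds, plan)
    rwz = pipe.eval_rho_w_zeta(enc)
    H = pipe.eval_H(enc, rwz.W)
    adj = pipe.eval_H_adj_det(H)
    zeta_star = pipe.eval_zeta_star(enc, rwz, adj)
    wz = pipe.mult_w_zeta_star(rwz.W, zeta_star)
    conv = pipe.convert_inputs(rwz.W, wz, adj.B1)
    num, den = pipe.eval_s_star_and_z_parts(enc, conv, adj)
    result = client_finalize(ctx, num, den, adj.det, ds.M, ds.ids)
    manifest = build_manifest(ctx, pipe, plan, enc, result, offsets,
                              time.time() - start)
    return RunOutput(result=result, manifest=manifest)
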