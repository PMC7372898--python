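"""An RNS variant of the CKKS approximate homomorphic-encryption scheme.

Messages are vectors of up to n/2 reals, embedded into the negacyclic ring by
the canonical embedding (evaluation at the odd powers of a primitive 2n-th
root of unity indexed by powers of 5) and scaled by an exact rational scaling
factor.  The ciphertext modulus is a product of word-size primes; rescaling
divides by the top prime (approximately 2^p), and key switching uses the CRT
decomposition of the switched polynomial, at a cost of l^2 native NTTs per
switch.  Scales are tracked as exact rationals (products of the actual primes
divided out), never as nominal powers of 2^p, and additions require exactly
matching scales -- there is no silent alignment; circuits align operands
explicitly through :meth:`CkksContext.level_reduce`.

Ciphertexts may carry more than two polynomials: multiplications may be
performed "lazily" without relinearization, letting the size grow, and
decryption evaluates sum_t c_t * s^t.  Relinearization keys for the needed
powers of the secret are generated up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .counters import OpCounters
from .rns import (EVAL, ModulusChain, RnsPoly, addmod, apply_automorphism,
                  drop_limb, generate_modulus_chain, intt, mulmod, ntt,
                  poly_add, poly_mul, poly_neg, poly_sub, rescale_poly)

_U64 = np.uint64


# ---------------------------------------------------------------------------
# Parameters and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseParams:
    """Distribution parameters: discrete Gaussian errors of std ``sigma``
    (3.19, the HE-standard value), ternary uniform secrets/encryption
    randomness, and a key-switch digit window ``w`` in bits (None = one full
    CRT limb, the setting used throughout)."""

    sigma: float = 3.19
    w_bits: Optional[int] = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class Plaintext:
    poly: RnsPoly            # evaluation form
    level: int
    scale: Fraction
    slots: int
    tag: str = "simd-vector"


@dataclass
class Ciphertext:
    """polys[t] is the coefficient of s^t in the decryption polynomial."""

    polys: list
    level: int
    scale: Fraction
    tag: str = "simd-vector"

    @property
    def size(self) -> int:
        return len(self.polys)

    def copy(self) -> "Ciphertext":
        return Ciphertext([p.copy() for p in self.polys], self.level,
                          self.scale, self.tag)


@dataclass
class SwitchKey:
    """CRT-decomposition switching key: one (b'_i, a'_i) pair per stored limb.

    Generated at the top level; :meth:`at_level` compresses to the working
    level by discarding pairs above it and dropping limbs of the rest.
    """

    pairs: list  # [(b_i, a_i)] RnsPolys in evaluation form
    stored_level: int

    def at_level(self, level: int) -> "SwitchKey":
        if level > self.stored_level:
            raise ValueError("switch key stored below requested level")
        if level == self.stored_level:
            return self
        pairs = [(drop_limb(b, b.level - level), drop_limb(a, a.level - level))
                 for (b, a) in self.pairs[:level]]
        return SwitchKey(pairs, level)

    def compress_to(self, level: int) -> None:
        """Irreversibly shrink the stored key to ``level`` limbs/pairs."""
        small = self.at_level(level)
        self.pairs = small.pairs
        self.stored_level = level


@dataclass
class KeySet:
    sk: RnsPoly                       # ternary secret, evaluation form, level L
    pk: tuple                         # (b, a)
    evk: dict = field(default_factory=dict)       # power t -> SwitchKey(s^t)
    rot_keys: dict = field(default_factory=dict)  # kappa -> SwitchKey(s^(kappa))


# ---------------------------------------------------------------------------
# Noise bounds (canonical-embedding heuristics)
# ---------------------------------------------------------------------------

def noise_bounds(kind: str, *, n: int, sigma: float = 3.19,
                 w: Optional[float] = None, q_top: Optional[float] = None,
                 B: float = 0.0, B1: float = 0.0, B2: float = 0.0,
                 nu1: float = 0.0, nu2: float = 0.0) -> float:
    """Closed-form heuristic noise bounds for the RNS scheme.

    kind: clean | scale | add | ksw | mult | rescale.
    ``w`` is the key-switch window (defaults to the top prime, i.e. one limb).
    """
    rn = float(n)
    if kind == "clean":
        return 6.0 * sigma * (4.0 * np.sqrt(3.0) * rn + np.sqrt(rn))
    if kind == "scale":
        return np.sqrt(3.0) * (12.0 * rn + np.sqrt(rn))
    if kind == "add":
        return B1 + B2
    if kind == "ksw":
        if q_top is None:
            raise ValueError("ksw bound needs q_top")
        ww = float(w) if w is not None else float(q_top)
        digits = int(np.ceil(np.log(q_top) / np.log(ww))) if ww > 1 else 1
        return (8.0 / np.sqrt(3.0)) * rn * sigma * ww * digits
    if kind == "mult":
        if q_top is None:
            raise ValueError("mult bound needs q_top for its ksw term")
        return nu1 * B2 + nu2 * B1 + B1 * B2 + noise_bounds(
            "ksw", n=n, sigma=sigma, w=w, q_top=q_top)
    if kind == "rescale":
        if q_top is None:
            raise ValueError("rescale bound needs q_top")
        return B / float(q_top) + noise_bounds("scale", n=n)
    raise ValueError(f"unknown noise bound kind: {kind!r}")


# ---------------------------------------------------------------------------
# Storage accounting (payload bytes of the limb-major 64-bit container)
# ---------------------------------------------------------------------------

def sizeof_poly(level: int, chain: ModulusChain) -> int:
    return level * chain.n * 8


def sizeof_ciphertext(level: int, chain: ModulusChain, n_polys: int = 2) -> int:
    return n_polys * sizeof_poly(level, chain)


def sizeof_switchkey(level: int, chain: ModulusChain) -> int:
    # `level` decomposition pairs, each a pair of `level`-limb polynomials
    return 2 * level * sizeof_poly(level, chain)


def sizeof_secret_key(chain: ModulusChain) -> int:
    # serialized as the pair (1, s) at the top level
    return 2 * sizeof_poly(chain.L, chain)


# ---------------------------------------------------------------------------
# Context
# ---------------------------------------------------------------------------

class CkksContext:
    """Holds a modulus chain, noise parameters, slot-embedding tables, a
    deterministic RNG, and (after :meth:`keygen`) the key set."""

    def __init__(self, chain: ModulusChain, noise: NoiseParams = NoiseParams(),
                 seed: int = 0):
        self.chain = chain
        self.noise = noise
        self.rng = np.random.default_rng(seed)
        self.keys: Optional[KeySet] = None
        n = chain.n
        # slot j <-> evaluation point psi^(5^j mod 2n); t-index (e-1)/2
        e = np.empty(n // 2, dtype=np.int64)
        acc = 1
        for j in range(n // 2):
            e[j] = acc
            acc = (acc * 5) % (2 * n)
        self._slot_t = (e - 1) // 2
        self._conj_t = n - 1 - self._slot_t
        k = np.arange(n)
        self._zeta_pows = np.exp(1j * np.pi * k / n)        # zeta^k
        self._inv_zeta_pows = np.exp(-1j * np.pi * k / n)

    @property
    def counters(self) -> OpCounters:
        return self.chain.counters

    @property
    def n_slots(self) -> int:
        return self.chain.n // 2

    # -- encoding ----------------------------------------------------------

    def embed(self, w: np.ndarray, scale: Fraction) -> np.ndarray:
        """Real slot vector -> integer coefficient vector (rounded)."""
        n = self.chain.n
        w = np.asarray(w, dtype=np.float64)
        if w.ndim != 1 or len(w) > n // 2:
            raise ValueError("need a 1-d vector of at most n/2 slots")
        full = np.zeros(n // 2, dtype=np.complex128)
        full[: len(w)] = w
        u = np.zeros(n, dtype=np.complex128)
        u[self._slot_t] = full
        u[self._conj_t] = np.conj(full)
        m = np.real(np.fft.fft(u) * self._inv_zeta_pows) / n
        fscale = float(scale)
        coeffs = np.rint(m * fscale)
        if np.max(np.abs(coeffs)) >= 2.0 ** 62:
            # exact big-integer rounding path for very large scales
            return np.array([int(round(x * fscale)) for x in m], dtype=object)
        return coeffs.astype(np.int64)

    def unembed(self, coeffs: Sequence[int], scale: Fraction) -> np.ndarray:
        """Integer coefficients -> real slot vector of length n/2."""
        n = self.chain.n
        m = np.array([float(c) for c in coeffs]) / float(scale)
        u = n * np.fft.ifft(m * self._zeta_pows)
        return np.real(u[self._slot_t])

    def encode(self, w, level: int, scale: Fraction,
               tag: str = "simd-vector") -> Plaintext:
        """Canonical-embedding encoding at the given level and exact scale."""
        scale = Fraction(scale)
        if np.isscalar(w):
            # constant slot vector == degree-0 polynomial: encode exactly
            # without any transform (its NTT is itself)
            val = float(w)
            if Fraction(max(abs(val), 1.0)) * scale * 4 > self.chain.Q(level):
                raise ValueError("encoded values would overflow Q_level")
            prod = Fraction(val) * scale
            c0 = (2 * prod.numerator + prod.denominator) // (
                2 * prod.denominator)
            res = np.empty((level, self.chain.n), dtype=_U64)
            for i in range(level):
                res[i, :] = c0 % int(self.chain.primes[i])
            return Plaintext(RnsPoly(self.chain, level, res, EVAL),
                             level, scale, self.n_slots, tag)
        w = np.asarray(w, dtype=np.float64)
        maxmag = float(np.max(np.abs(w))) if w.size else 0.0
        if Fraction(max(maxmag, 1.0)) * scale * 4 > self.chain.Q(level):
            raise ValueError("encoded values would overflow Q_level")
        coeffs = self.embed(w, scale)
        poly = RnsPoly.from_int_coeffs(self.chain, level, list(coeffs))
        return Plaintext(ntt(poly), level, scale, len(w), tag)

    def decode(self, pt: Plaintext) -> np.ndarray:
        coeffs = intt(pt.poly).to_int_coeffs(centered=True)
        return self.unembed(coeffs, pt.scale)[: self.n_slots]

    # -- sampling ----------------------------------------------------------

    def _ternary(self, level: int) -> RnsPoly:
        c = self.rng.integers(-1, 2, self.chain.n)
        return ntt(RnsPoly.from_int_coeffs(self.chain, level, c))

    def _gaussian(self, level: int) -> RnsPoly:
        c = np.rint(self.rng.normal(0.0, self.noise.sigma, self.chain.n))
        return ntt(RnsPoly.from_int_coeffs(self.chain, level,
                                           c.astype(np.int64)))

    def _uniform(self, level: int) -> RnsPoly:
        res = np.empty((level, self.chain.n), dtype=_U64)
        for i in range(level):
            res[i] = self.rng.integers(0, self.chain.primes[i], self.chain.n,
                                       dtype=np.uint64)
        return RnsPoly(self.chain, level, res, EVAL)

    # -- key generation ----------------------------------------------------

    def keygen(self, rotation_indices: Sequence[int] = (),
               relin_powers: Sequence[int] = (2,),
               rotation_levels: Optional[dict] = None,
               relin_levels: Optional[dict] = None) -> KeySet:
        """Generate secret/public keys, relinearization keys for the given
        powers of s, and rotation keys for the given slot offsets.

        ``rotation_levels`` / ``relin_levels`` optionally cap each switch key
        at its maximum use level (fewer pairs/limbs to generate and store);
        omitted entries default to the top of the chain.
        """
        L = self.chain.L
        s = self._ternary(L)
        a = self._uniform(L)
        e = self._gaussian(L)
        b = poly_sub(e, poly_mul(a, s))
        keys = KeySet(sk=s, pk=(b, a))
        for t in sorted(set(relin_powers)):
            sp = s
            for _ in range(t - 1):
                sp = poly_mul(sp, s)
            keys.evk[t] = self._ksgen(s, sp, (relin_levels or {}).get(t, L))
        for kappa in rotation_indices:
            keys.rot_keys[int(kappa)] = self._ksgen(
                s, apply_automorphism(s, self._rotation_exponent(kappa)),
                (rotation_levels or {}).get(int(kappa), L))
        self.keys = keys
        return keys

    def _rotation_exponent(self, kappa: int) -> int:
        return pow(5, kappa % (self.chain.n // 2), 2 * self.chain.n)

    def _ksgen(self, s: RnsPoly, s_prime: RnsPoly,
               level: Optional[int] = None) -> SwitchKey:
        """swk_i = (-a'_i s + e'_i + q~_i q*_i s', a'_i) at ``level``.

        The CRT constant q~_i q*_i has residue 1 at limb i and 0 elsewhere,
        so the s' term touches only limb i.
        """
        level = self.chain.L if level is None else level
        if not (1 <= level <= self.chain.L):
            raise ValueError("switch-key level outside the chain")
        s_l = drop_limb(s, s.level - level)
        sp_l = drop_limb(s_prime, s_prime.level - level)
        pairs = []
        for i in range(level):
            ai = self._uniform(level)
            ei = self._gaussian(level)
            bi = poly_sub(ei, poly_mul(ai, s_l))
            bi.residues[i] = addmod(bi.residues[i], sp_l.residues[i],
                                    self.chain.moduli[i])
            pairs.append((bi, ai))
        return SwitchKey(pairs, level)

    # -- encryption / decryption -------------------------------------------

    def encrypt(self, pt: Plaintext) -> Ciphertext:
        if self.keys is None:
            raise RuntimeError("keygen first")
        if pt.level > self.chain.L:
            raise ValueError("plaintext level above chain top")
        lv = pt.level
        b = drop_limb(self.keys.pk[0], self.chain.L - lv)
        a = drop_limb(self.keys.pk[1], self.chain.L - lv)
        v = self._ternary(lv)
        e0 = self._gaussian(lv)
        e1 = self._gaussian(lv)
        c0 = poly_add(poly_add(poly_mul(v, b), e0), pt.poly)
        c1 = poly_add(poly_mul(v, a), e1)
        return Ciphertext([c0, c1], lv, pt.scale, pt.tag)

    def encrypt_vector(self, w, level: Optional[int] = None,
                       scale: Optional[Fraction] = None,
                       tag: str = "simd-vector") -> Ciphertext:
        level = self.chain.L if level is None else level
        scale = Fraction(2) ** self.chain.p if scale is None else Fraction(scale)
        return self.encrypt(self.encode(w, level, scale, tag))

    def decrypt(self, ct: Ciphertext) -> Plaintext:
        if self.keys is None:
            raise RuntimeError("keygen first")
        s = drop_limb(self.keys.sk, self.chain.L - ct.level)
        acc = ct.polys[0]
        spow = None
        for t in range(1, ct.size):
            spow = s if spow is None else poly_mul(spow, s)
            acc = poly_add(acc, poly_mul(ct.polys[t], spow))
        return Plaintext(acc, ct.level, ct.scale, self.n_slots, ct.tag)

    def decrypt_vector(self, ct: Ciphertext) -> np.ndarray:
        return self.decode(self.decrypt(ct))

    # -- arithmetic --------------------------------------------------------

    def _check_pair(self, ct1: Ciphertext, ct2: Ciphertext,
                    check_scale: bool = True) -> None:
        if ct1.level != ct2.level:
            raise ValueError(f"level mismatch {ct1.level} vs {ct2.level}")
        if check_scale and ct1.scale != ct2.scale:
            raise ValueError("scale mismatch (no silent alignment)")

    def add(self, ct1: Ciphertext, ct2: Ciphertext) -> Ciphertext:
        self._check_pair(ct1, ct2)
        n = max(ct1.size, ct2.size)
        polys = []
        for t in range(n):
            if t < ct1.size and t < ct2.size:
                polys.append(poly_add(ct1.polys[t], ct2.polys[t]))
            elif t < ct1.size:
                polys.append(ct1.polys[t].copy())
            else:
                polys.append(ct2.polys[t].copy())
        return Ciphertext(polys, ct1.level, ct1.scale, ct1.tag)

    def sub(self, ct1: Ciphertext, ct2: Ciphertext) -> Ciphertext:
        neg = Ciphertext([poly_neg(p) for p in ct2.polys], ct2.level,
                         ct2.scale, ct2.tag)
        return self.add(ct1, neg)

    def cadd(self, ct: Ciphertext, const) -> Ciphertext:
        """Add a scalar or slot vector, encoded at the ciphertext's scale."""
        pt = self.encode(const, ct.level, ct.scale)
        out = ct.copy()
        out.polys[0] = poly_add(out.polys[0], pt.poly)
        return out

    def cmult(self, ct: Ciphertext, pt: Plaintext,
              is_mask: bool = False) -> Ciphertext:
        """Plaintext-ciphertext product; scales multiply."""
        if pt.level != ct.level:
            raise ValueError("plaintext level must match ciphertext level")
        polys = [poly_mul(p, pt.poly) for p in ct.polys]
        if is_mask:
            self.counters.count_mask_mult()
        else:
            self.counters.count_simd_mult()
        return Ciphertext(polys, ct.level, ct.scale * pt.scale, ct.tag)

    def cmult_raw(self, ct: Ciphertext, values, scale: Fraction,
                  is_mask: bool = False) -> Ciphertext:
        return self.cmult(ct, self.encode(values, ct.level, Fraction(scale)),
                          is_mask=is_mask)

    def mult(self, ct1: Ciphertext, ct2: Ciphertext,
             relin: bool = False) -> Ciphertext:
        """Homomorphic product; without relinearization the size grows to
        size1 + size2 - 1 (decryption evaluates the polynomial in s)."""
        self._check_pair(ct1, ct2, check_scale=False)
        out_size = ct1.size + ct2.size - 1
        polys = [None] * out_size
        for i, p in enumerate(ct1.polys):
            for j, q in enumerate(ct2.polys):
                prod = poly_mul(p, q)
                polys[i + j] = prod if polys[i + j] is None \
                    else poly_add(polys[i + j], prod)
        self.counters.count_simd_mult()
        out = Ciphertext(polys, ct1.level, ct1.scale * ct2.scale, ct1.tag)
        if relin:
            out = self.relinearize(out)
        return out

    # -- key switching -----------------------------------------------------

    def _decompose(self, d: RnsPoly) -> list:
        """CRT decomposition of an evaluation-form polynomial.

        Component i is the integer polynomial with coefficients d mod q_i,
        lifted back to all limbs.  Costs exactly l + l(l-1) = l^2 native
        NTTs: one batched inverse transform plus l-1 forward transforms per
        component (the limb-i row of component i is the original limb).
        """
        chain = self.chain
        lv = d.level
        coeff = intt(d)  # l native NTTs
        comps = []
        for i in range(lv):
            ci = coeff.residues[i]  # integers in [0, q_i)
            rows = np.empty((lv, chain.n), dtype=_U64)
            for j in range(lv):
                if j == i:
                    rows[j] = d.residues[i]
                else:
                    rows[j] = np.mod(ci, chain.moduli[j])
            # transform rows j != i to evaluation form with limb-j tables
            comp = self._rows_ntt_skip(rows, lv, skip=i)
            comps.append(RnsPoly(chain, lv, comp, EVAL))
        return comps

    def _rows_ntt_skip(self, rows: np.ndarray, lv: int, skip: int) -> np.ndarray:
        """Forward-transform all rows except ``skip`` (already evaluation)."""
        from .rns import _cyclic_fft
        chain = self.chain
        t = chain._tables
        idx = [j for j in range(lv) if j != skip]
        if idx:
            m = chain.moduli[idx][:, None]
            a = mulmod(rows[idx], t.psi_pows[idx], m)
            a = _cyclic_fft(a, t.omega_pows[idx], m, chain.n)
            out = rows.copy()
            out[idx] = a
            chain.counters.count_ntt(len(idx))
        else:
            out = rows.copy()
        return out

    def _inner_product(self, comps: list, swk: SwitchKey) -> tuple:
        lv = comps[0].level
        key = swk.at_level(lv)
        b_acc = None
        a_acc = None
        for comp, (bi, ai) in zip(comps, key.pairs):
            tb = poly_mul(comp, bi)
            ta = poly_mul(comp, ai)
            b_acc = tb if b_acc is None else poly_add(b_acc, tb)
            a_acc = ta if a_acc is None else poly_add(a_acc, ta)
        return b_acc, a_acc

    def relinearize(self, ct: Ciphertext) -> Ciphertext:
        """Switch every s^t component (t >= 2) back to the base key.

        Counted as a single relinearization operation regardless of the
        input size (one key-switch per extra component internally).
        """
        if ct.size <= 2:
            return ct
        if self.keys is None:
            raise RuntimeError("keygen first")
        c0, c1 = ct.polys[0], ct.polys[1]
        for t in range(2, ct.size):
            swk = self.keys.evk.get(t)
            if swk is None:
                raise KeyError(f"no relinearization key for power {t}")
            comps = self._decompose(ct.polys[t])
            db, da = self._inner_product(comps, swk)
            c0 = poly_add(c0, db)
            c1 = poly_add(c1, da)
        self.counters.count_relin()
        return Ciphertext([c0, c1], ct.level, ct.scale, ct.tag)

    def rotate(self, ct: Ciphertext, kappa: int) -> Ciphertext:
        """Cyclic slot rotation by kappa (slot j takes the value of slot
        j+kappa); 2-poly ciphertexts only."""
        if kappa % self.n_slots == 0:
            return ct.copy()
        if ct.size != 2:
            raise ValueError("rotation requires a relinearized ciphertext")
        if self.keys is None or int(kappa) not in self.keys.rot_keys:
            raise KeyError(f"missing rotation key for offset {kappa}")
        g = self._rotation_exponent(kappa)
        b = apply_automorphism(ct.polys[0], g)
        a = apply_automorphism(ct.polys[1], g)
        comps = self._decompose(a)
        db, da = self._inner_product(comps, self.keys.rot_keys[int(kappa)])
        self.counters.count_rotation()
        return Ciphertext([poly_add(b, db), da], ct.level, ct.scale, ct.tag)

    def hoist_decompose(self, ct: Ciphertext) -> list:
        """Precompute the CRT decomposition of c1 once for many rotations."""
        if ct.size != 2:
            raise ValueError("hoisting requires a relinearized ciphertext")
        return self._decompose(ct.polys[1])

    def hoisted_rotate(self, ct: Ciphertext, comps: list,
                       kappa: int) -> Ciphertext:
        """Rotation sharing a precomputed decomposition: the automorphism is
        applied to the decomposed components (a slot permutation in
        evaluation form), so no additional NTTs are needed."""
        if kappa % self.n_slots == 0:
            return ct.copy()
        if self.keys is None or int(kappa) not in self.keys.rot_keys:
            raise KeyError(f"missing rotation key for offset {kappa}")
        g = self._rotation_exponent(kappa)
        b = apply_automorphism(ct.polys[0], g)
        rcomps = [apply_automorphism(c, g) for c in comps]
        db, da = self._inner_product(rcomps, self.keys.rot_keys[int(kappa)])
        self.counters.count_rotation()
        return Ciphertext([poly_add(b, db), da], ct.level, ct.scale, ct.tag)

    def hoisted_rotations(self, ct: Ciphertext, kappas: Sequence[int]) -> list:
        comps = self.hoist_decompose(ct)
        return [self.hoisted_rotate(ct, comps, k) for k in kappas]

    # -- rescaling and level management -------------------------------------

    def rescale(self, ct: Ciphertext) -> Ciphertext:
        """Divide by the top prime; level drops by one and the tracked scale
        is divided by q_l exactly."""
        if ct.level < 2:
            raise ValueError("cannot rescale a level-1 ciphertext")
        q_top = self.chain.primes[ct.level - 1]
        # rescale_poly counts one rescale (and l native NTTs) per polynomial
        polys = [rescale_poly(p) for p in ct.polys]
        return Ciphertext(polys, ct.level - 1, ct.scale / q_top, ct.tag)

    def drop_to_level(self, ct: Ciphertext, level: int) -> Ciphertext:
        """Discard top limbs without scaling (scale unchanged)."""
        if level > ct.level or level < 1:
            raise ValueError("invalid target level")
        if level == ct.level:
            return ct.copy()
        cnt = ct.level - level
        return Ciphertext([drop_limb(p, cnt) for p in ct.polys], level,
                          ct.scale, ct.tag)

    def level_reduce(self, ct: Ciphertext, level: int,
                     scale: Fraction) -> Ciphertext:
        """Bring ``ct`` to (level, scale) exactly.

        If the scale already matches, limbs are simply dropped.  Otherwise
        one constant multiplication (by 1, encoded at the exact correcting
        scale) plus a single rescale realises the adjustment; the constant's
        scale is chosen so the result's exact rational scale equals the
        target.
        """
        scale = Fraction(scale)
        if level > ct.level:
            raise ValueError("cannot raise level")
        if ct.scale == scale:
            return self.drop_to_level(ct, level)
        if level >= ct.level:
            raise ValueError("scale change requires at least one spare level")
        work = self.drop_to_level(ct, level + 1)
        q_top = self.chain.primes[level]
        const_scale = scale * q_top / work.scale
        if const_scale <= 0:
            raise ValueError("cannot align to a smaller scale")
        pt = self.encode(1.0, work.level, const_scale)
        work = self.cmult(work, pt)
        work = self.rescale(work)
        assert work.scale == scale
        return work


def toy_context(n: int = 64, p: int = 30, L: int = 5, seed: int = 0,
                sigma: float = 3.19) -> CkksContext:
    """Small-parameter context for tests and examples (no lattice security)."""
    chain = generate_modulus_chain(p, n, L)
    return CkksContext(chain, NoiseParams(sigma=sigma), seed=seed)
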