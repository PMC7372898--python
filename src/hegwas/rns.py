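"""Exact polynomial arithmetic in R_l = Z_{Q_l}[x]/<x^n + 1> in residue form.

A ring element is held as an ``l x n`` matrix of 64-bit residues, one row per
prime of the modulus chain ("double-CRT" / RNS representation).  All modular
arithmetic is exact: products of 64-bit residues are reduced with a vectorised
float-quotient Barrett step whose +-1 quotient error is corrected, which is
exact for moduli below 2^51 (the chain enforces this bound; the scheme uses
scaling factors of at most 50 bits).

The negacyclic number-theoretic transform (NTT) per limb converts between the
coefficient representation and the evaluation representation at the odd powers
of a primitive 2n-th root of unity, enabling pointwise multiplication.  Every
native (single-limb) transform is counted through the chain's counters so that
complexity claims can be asserted by tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import sympy

from .counters import OpCounters

_U64 = np.uint64
_MAX_MODULUS_BITS = 51  # float-Barrett exactness bound


# ---------------------------------------------------------------------------
# Vectorised exact modular arithmetic
# ---------------------------------------------------------------------------

try:
    import numba as _numba
    _HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba ships with the env
    _HAVE_NUMBA = False


if _HAVE_NUMBA:
    @_numba.njit(cache=True)
    def _mulmod_rows(a, b, m_vec, out):
        lv, n = a.shape
        for i in range(lv):
            m = m_vec[i]
            inv_m = 1.0 / m
            for j in range(n):
                x = a[i, j]
                y = b[i, j]
                q = np.uint64(x * inv_m * y)
                r = x * y - q * m + m   # true value in [0, 3m), wraps exactly
                if r >= m:
                    r -= m
                if r >= m:
                    r -= m
                out[i, j] = r

    @_numba.njit(cache=True)
    def _addmod_rows(a, b, m_vec, out):
        lv, n = a.shape
        for i in range(lv):
            m = m_vec[i]
            for j in range(n):
                r = a[i, j] + b[i, j]
                if r >= m:
                    r -= m
                out[i, j] = r

    @_numba.njit(cache=True)
    def _submod_rows(a, b, m_vec, out):
        lv, n = a.shape
        for i in range(lv):
            m = m_vec[i]
            for j in range(n):
                x = a[i, j]
                y = b[i, j]
                out[i, j] = x - y if x >= y else x - y + m


def _rows_kernel_args(a, b, m):
    """Broadcast operands for the per-row kernels; None if shapes don't fit
    the (limbs, n) x per-limb-modulus pattern."""
    if a.ndim != 2 or m.ndim != 2 or m.shape != (a.shape[0], 1):
        return None
    try:
        shape = np.broadcast_shapes(a.shape, b.shape)
    except ValueError:
        return None
    if shape[0] != a.shape[0]:
        return None
    aa = np.ascontiguousarray(np.broadcast_to(a, shape))
    bb = np.ascontiguousarray(np.broadcast_to(b, shape))
    return aa, bb, m.reshape(-1), np.empty(shape, dtype=_U64)


def mulmod(a: np.ndarray, b: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Exact (a * b) mod m elementwise for m < 2^51.

    The quotient is estimated in float64 (error at most 1 for 51-bit moduli)
    and the remainder recovered with wrap-around uint64 arithmetic, then
    corrected into [0, m).
    """
    a = np.asarray(a, dtype=_U64)
    b = np.asarray(b, dtype=_U64)
    m = np.asarray(m, dtype=_U64)
    if _HAVE_NUMBA:
        args = _rows_kernel_args(a, b, m)
        if args is not None:
            _mulmod_rows(*args)
            return args[3]
    # reciprocal multiply instead of division: the quotient error stays
    # below one for 51-bit moduli, absorbed by the corrections below
    q = (a.astype(np.float64) * b.astype(np.float64)
         * (1.0 / m.astype(np.float64))).astype(_U64)
    with np.errstate(over="ignore"):
        r = a * b - q * m + m  # true value in [0, 3m), exact mod 2^64
    r = np.where(r >= m, r - m, r)
    r = np.where(r >= m, r - m, r)
    return r


def addmod(a: np.ndarray, b: np.ndarray, m: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=_U64)
    b = np.asarray(b, dtype=_U64)
    m = np.asarray(m, dtype=_U64)
    if _HAVE_NUMBA:
        args = _rows_kernel_args(a, b, m)
        if args is not None:
            _addmod_rows(*args)
            return args[3]
    r = a + b
    return np.where(r >= m, r - m, r)


def submod(a: np.ndarray, b: np.ndarray, m: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=_U64)
    b = np.asarray(b, dtype=_U64)
    m = np.asarray(m, dtype=_U64)
    if _HAVE_NUMBA:
        args = _rows_kernel_args(a, b, m)
        if args is not None:
            _submod_rows(*args)
            return args[3]
    with np.errstate(over="ignore"):
        r = a - b
    return np.where(a >= b, r, r + m)


def _powmod_table(base: int, length: int, modulus: int) -> np.ndarray:
    """[base^0, base^1, ..., base^(length-1)] mod modulus as uint64."""
    out = np.empty(length, dtype=_U64)
    acc = 1
    for i in range(length):
        out[i] = acc
        acc = (acc * base) % modulus
    return out


# ---------------------------------------------------------------------------
# Modulus chain
# ---------------------------------------------------------------------------

def _find_primitive_2n_root(q: int, n: int) -> int:
    """Smallest c >= 2 with psi = c^((q-1)/2n) satisfying psi^n = -1 mod q."""
    exp = (q - 1) // (2 * n)
    for c in range(2, 10_000):
        psi = pow(c, exp, q)
        if pow(psi, n, q) == q - 1:
            return psi
    raise RuntimeError(f"no primitive 2n-th root found for q={q}")


@dataclass(frozen=True)
class NttTables:
    """Per-limb negacyclic NTT tables (psi the primitive 2n-th root)."""

    psi_pows: np.ndarray       # (l, n) psi^k for premultiplication
    inv_psi_pows: np.ndarray   # (l, n) psi^-k
    omega_pows: np.ndarray     # (l, n) omega^k, omega = psi^2
    inv_omega_pows: np.ndarray
    n_inv: np.ndarray          # (l,) n^-1 mod q_i
    bitrev: np.ndarray         # (n,) bit-reversal permutation


class ModulusChain:
    """Chain of NTT-friendly word-size primes approximating 2^p.

    Each prime satisfies q_i = 1 (mod 2n) so that a negacyclic NTT of length
    n exists modulo q_i, and the signs of q_i - 2^p alternate along the chain
    so rescaling errors tend to cancel in deep circuits.  ``eps`` is the
    largest integer with 2^p / q_i in (1 - 2^-eps, 1 + 2^-eps) for every q_i.
    """

    def __init__(self, n: int, p: int, primes: list[int],
                 counters: Optional[OpCounters] = None):
        if n < 2 or n & (n - 1):
            raise ValueError("ring dimension n must be a power of two >= 2")
        self.n = n
        self.p = p
        self.L = len(primes)
        self.primes = tuple(int(q) for q in primes)
        self.moduli = np.array(self.primes, dtype=_U64)
        self.counters = counters if counters is not None else OpCounters()
        self.eps = self._precision_bound()
        self._tables = self._build_tables()
        self._auto_perm_cache: dict[tuple[int, str], np.ndarray] = {}
        self._rescale_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    # -- construction ------------------------------------------------------

    def _precision_bound(self) -> int:
        worst = max(abs(q - (1 << self.p)) / (1 << self.p) for q in self.primes)
        if worst == 0:
            return self.p
        eps = 0
        while 2.0 ** (-(eps + 1)) > worst:
            eps += 1
        # largest eps with |q/2^p - 1| < 2^-eps for all q
        while 2.0 ** (-eps) <= worst:
            eps -= 1
        return eps

    def _build_tables(self) -> NttTables:
        n, L = self.n, self.L
        psi_pows = np.empty((L, n), dtype=_U64)
        inv_psi = np.empty((L, n), dtype=_U64)
        omega_pows = np.empty((L, n), dtype=_U64)
        inv_omega = np.empty((L, n), dtype=_U64)
        n_inv = np.empty(L, dtype=_U64)
        for i, q in enumerate(self.primes):
            psi = _find_primitive_2n_root(q, n)
            psi_inv = pow(psi, -1, q)
            omega = (psi * psi) % q
            omega_inv = pow(omega, -1, q)
            psi_pows[i] = _powmod_table(psi, n, q)
            inv_psi[i] = _powmod_table(psi_inv, n, q)
            omega_pows[i] = _powmod_table(omega, n, q)
            inv_omega[i] = _powmod_table(omega_inv, n, q)
            n_inv[i] = pow(n, -1, q)
        bits = n.bit_length() - 1
        idx = np.arange(n)
        rev = np.zeros(n, dtype=np.int64)
        for b in range(bits):
            rev |= ((idx >> b) & 1) << (bits - 1 - b)
        return NttTables(psi_pows, inv_psi, omega_pows, inv_omega, n_inv, rev)

    # -- level helpers -----------------------------------------------------

    def Q(self, level: int) -> int:
        """Product of the first ``level`` primes (the ciphertext modulus)."""
        out = 1
        for q in self.primes[:level]:
            out *= q
        return out

    def automorphism_perm(self, g: int, form: str) -> np.ndarray:
        """Index permutation realising a(x) -> a(x^g) in the given form.

        In evaluation form the map is a pure permutation of the evaluation
        points; in coefficient form it is a signed permutation and the signs
        are returned alongside (coded into a second array by the caller via
        :func:`apply_automorphism`).
        """
        key = (g % (2 * self.n), form)
        if key not in self._auto_perm_cache:
            n = self.n
            if form == "eval":
                t = np.arange(n)
                src = ((g * (2 * t + 1)) % (2 * n) - 1) // 2
                self._auto_perm_cache[key] = src.astype(np.int64)
            else:
                raise ValueError("permutation tables cached for eval form only")
        return self._auto_perm_cache[key]

    def rescale_constants(self, level: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-limb constants for rescaling from ``level`` to ``level - 1``.

        Returns ``(qinv, dres)`` where ``qinv[i] = q_level^-1 mod q_i`` and
        ``dres[i] = floor(q~_level * Q_{level-1} / q_level) mod q_i`` for
        i < level - 1 ... (arrays of length level-1).
        """
        if level not in self._rescale_cache:
            ql = self.primes[level - 1]
            Qlm1 = self.Q(level - 1)
            qtilde = pow(Qlm1 % ql, -1, ql)  # (Q_l / q_l)^-1 mod q_l
            D = (qtilde * Qlm1) // ql
            qinv = np.array([pow(ql, -1, self.primes[i])
                             for i in range(level - 1)], dtype=_U64)
            dres = np.array([D % self.primes[i]
                             for i in range(level - 1)], dtype=_U64)
            self._rescale_cache[level] = (qinv, dres)
        return self._rescale_cache[level]

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ModulusChain(n={self.n}, p={self.p}, L={self.L}, "
                f"eps={self.eps})")


def generate_modulus_chain(p: int, n: int, L: int,
                           counters: Optional[OpCounters] = None,
                           search_bound: int = 1 << 28) -> ModulusChain:
    """Greedy alternating prime selection around 2^p.

    The first prime is the unused prime = 1 (mod 2n) globally nearest to 2^p;
    each subsequent prime is the nearest unused one on the opposite side of
    2^p from its predecessor, so the signs of q_i - 2^p alternate.
    """
    if n < 2 or n & (n - 1):
        raise ValueError("n must be a power of two")
    if (1 << p) <= 2 * n:
        raise ValueError("need 2n < 2^p for NTT-friendly primes near 2^p")
    if p > _MAX_MODULUS_BITS - 1:
        raise ValueError(f"scaling bits p must be <= {_MAX_MODULUS_BITS - 1}")
    if L < 1:
        raise ValueError("need at least one prime")
    target = 1 << p
    step = 2 * n

    def primes_on_side(side: int):
        """Yield primes = 1 mod 2n on the given side of 2^p, nearest first."""
        # candidates are target + r + j*step (above) or target + r - step*j (below)
        r = (1 - target) % step  # smallest r >= 0 with target + r = 1 mod 2n
        if side > 0:
            c = target + r
            if c == target:
                c += step
            while c < target + search_bound:
                if sympy.isprime(c):
                    yield c
                c += step
        else:
            c = target + r - step
            while c > target - search_bound and c > step:
                if sympy.isprime(c):
                    yield c
                c -= step

    above = primes_on_side(+1)
    below = primes_on_side(-1)
    primes: list[int] = []
    # first prime: globally nearest
    a = next(above, None)
    b = next(below, None)
    if a is None and b is None:
        raise ValueError("no suitable primes within search bound")
    if b is None or (a is not None and a - target <= target - b):
        primes.append(a)
        side = -1
        if b is not None:  # peeked but unused; push back
            below = itertools.chain([b], below)
    else:
        primes.append(b)
        side = +1
        if a is not None:
            above = itertools.chain([a], above)
    while len(primes) < L:
        nxt = next(above if side > 0 else below, None)
        if nxt is None:
            raise ValueError(
                f"could not find {L} alternating primes within search bound")
        primes.append(nxt)
        side = -side
    return ModulusChain(n, p, primes, counters)


# ---------------------------------------------------------------------------
# Ring elements
# ---------------------------------------------------------------------------

COEFF = "coeff"
EVAL = "eval"


@dataclass
class RnsPoly:
    """A ring element at a given level, in coefficient or evaluation form."""

    chain: ModulusChain
    level: int
    residues: np.ndarray  # (level, n) uint64
    form: str = COEFF

    def __post_init__(self):
        if self.residues.shape != (self.level, self.chain.n):
            raise ValueError("residue matrix shape does not match level/n")
        if self.form not in (COEFF, EVAL):
            raise ValueError(f"unknown form {self.form!r}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def zero(cls, chain: ModulusChain, level: int, form: str = COEFF):
        return cls(chain, level,
                   np.zeros((level, chain.n), dtype=_U64), form)

    @classmethod
    def from_int_coeffs(cls, chain: ModulusChain, level: int, coeffs):
        """Build from signed integer coefficients (Python ints or int64)."""
        if isinstance(coeffs, np.ndarray) and coeffs.dtype.kind in "iu":
            if coeffs.shape != (chain.n,):
                raise ValueError("need exactly n coefficients")
            a64 = coeffs.astype(np.int64)
            res = np.empty((level, chain.n), dtype=_U64)
            for i in range(level):
                res[i] = np.mod(a64, chain.primes[i]).astype(_U64)
            return cls(chain, level, res, COEFF)
        arr = np.asarray(coeffs, dtype=object)
        if arr.shape != (chain.n,):
            raise ValueError("need exactly n coefficients")
        res = np.empty((level, chain.n), dtype=_U64)
        small = all(isinstance(c, (int, np.integer)) and -2**62 < int(c) < 2**62
                    for c in arr.flat)
        if small:
            a64 = arr.astype(np.int64)
            for i in range(level):
                q = chain.primes[i]
                res[i] = np.mod(a64, q).astype(_U64)
        else:
            for i in range(level):
                q = chain.primes[i]
                res[i] = np.array([int(c) % q for c in arr], dtype=_U64)
        return cls(chain, level, res, COEFF)

    # -- CRT composition (multiprecision, for encode/decode and oracles) ----

    def to_int_coeffs(self, centered: bool = True) -> list[int]:
        """Compose residues into integers mod Q_level (coefficient form)."""
        if self.form != COEFF:
            raise ValueError("compose requires coefficient form")
        Q = self.chain.Q(self.level)
        if self.level == 1:
            vals = [int(v) for v in self.residues[0]]
        else:
            vals = [0] * self.chain.n
            for i in range(self.level):
                q = self.chain.primes[i]
                qi_star = Q // q
                qi_tilde = pow(qi_star % q, -1, q)
                mult = (qi_star * qi_tilde) % Q
                row = self.residues[i]
                for j in range(self.chain.n):
                    vals[j] = (vals[j] + int(row[j]) * mult) % Q
        if centered:
            half = Q // 2
            vals = [v - Q if v > half else v for v in vals]
        return vals

    # -- form conversion ---------------------------------------------------

    def _check_binary(self, other: "RnsPoly", need_form: Optional[str] = None):
        if self.level != other.level:
            raise ValueError(
                f"level mismatch: {self.level} vs {other.level}")
        if self.form != other.form:
            raise ValueError(f"form mismatch: {self.form} vs {other.form}")
        if need_form is not None and self.form != need_form:
            raise ValueError(f"operation requires {need_form} form")

    def copy(self) -> "RnsPoly":
        return RnsPoly(self.chain, self.level, self.residues.copy(), self.form)


def ntt(poly: RnsPoly) -> RnsPoly:
    """Negacyclic forward transform of every limb (counts ``level`` NTTs)."""
    if poly.form != COEFF:
        raise ValueError("ntt requires coefficient form")
    chain = poly.chain
    t = chain._tables
    lv = poly.level
    m = chain.moduli[:lv, None]
    a = mulmod(poly.residues, t.psi_pows[:lv], m)
    a = _cyclic_fft(a, t.omega_pows[:lv], m, chain.n)
    chain.counters.count_ntt(lv)
    return RnsPoly(chain, lv, a, EVAL)


def intt(poly: RnsPoly) -> RnsPoly:
    """Inverse negacyclic transform of every limb."""
    if poly.form != EVAL:
        raise ValueError("intt requires evaluation form")
    chain = poly.chain
    t = chain._tables
    lv = poly.level
    m = chain.moduli[:lv, None]
    a = _cyclic_fft(poly.residues, t.inv_omega_pows[:lv], m, chain.n)
    a = mulmod(a, t.n_inv[:lv, None], m)
    a = mulmod(a, t.inv_psi_pows[:lv], m)
    chain.counters.count_ntt(lv)
    return RnsPoly(chain, lv, a, COEFF)


def _limb_intt(chain: ModulusChain, limb: int, row: np.ndarray) -> np.ndarray:
    """Inverse negacyclic transform of one limb using that limb's tables."""
    t = chain._tables
    m = chain.moduli[limb:limb + 1, None]
    a = _cyclic_fft(row[None, :].copy(), t.inv_omega_pows[limb:limb + 1],
                    m, chain.n)
    a = mulmod(a, t.n_inv[limb:limb + 1, None], m)
    a = mulmod(a, t.inv_psi_pows[limb:limb + 1], m)
    chain.counters.count_ntt(1)
    return a[0]


if _HAVE_NUMBA:
    @_numba.njit(cache=True)
    def _fft_rows_kernel(a, omega, w_over_m, m_vec, n):
        """In-place radix-2 DIT over bit-reversed rows, one modulus per row.

        Products are reduced with the reciprocal quotient trunc(v*(w/m)-1/2),
        which is q_true or q_true-1 for m < 2^50.5, so one conditional
        subtract finishes the reduction; uint64 arithmetic wraps consistently.
        """
        lv = a.shape[0]
        for i in range(lv):
            m = m_vec[i]
            row = a[i]
            om = omega[i]
            wm = w_over_m[i]
            size = 2
            while size <= n:
                half = size >> 1
                stride = n // size
                for b0 in range(0, n, size):
                    for j in range(half):
                        w = om[j * stride]
                        wmj = wm[j * stride]
                        v = row[b0 + half + j]
                        q = np.uint64(np.int64(v * wmj - 0.5))
                        t = v * w - q * m
                        if t >= m:
                            t -= m
                        u = row[b0 + j]
                        s = u + t
                        if s >= m:
                            s -= m
                        d = u - t
                        if u < t:
                            d += m
                        row[b0 + j] = s
                        row[b0 + half + j] = d
                size <<= 1


def _reciprocal_table(omega_pows: np.ndarray, m: np.ndarray) -> np.ndarray:
    """omega/m in float64, feeding the reciprocal quotient estimate."""
    return omega_pows.astype(np.float64) / m.astype(np.float64)


def _cyclic_fft(a: np.ndarray, omega_pows: np.ndarray, m: np.ndarray,
                n: int) -> np.ndarray:
    """Iterative radix-2 DIT cyclic DFT over each limb, natural-order output.

    ``omega_pows[i, k]`` holds omega_i^k; twiddles for a stage of size ``s``
    are the powers with stride n/s.  A compiled kernel does the butterflies;
    the vectorised numpy path below is the fallback (and the reference the
    tests compare against).
    """
    a = np.ascontiguousarray(a[:, _bitrev_perm(n)])
    w_over_m = _reciprocal_table(omega_pows, m)
    if _HAVE_NUMBA:
        _fft_rows_kernel(a, omega_pows, w_over_m, m.reshape(-1), n)
        return a
    return _cyclic_fft_numpy(a, omega_pows, w_over_m, m, n)


def _cyclic_fft_numpy(a: np.ndarray, omega_pows: np.ndarray,
                      w_over_m: np.ndarray, m: np.ndarray,
                      n: int) -> np.ndarray:
    """Pure-numpy butterflies on an already bit-reversed matrix."""
    lv = a.shape[0]
    with np.errstate(over="ignore"):
        size = 2
        while size <= n:
            half = size // 2
            stride = n // size
            sl = np.s_[:, : half * stride : stride]
            w = omega_pows[sl][:, None, :]           # (lv, 1, half)
            wm = w_over_m[sl][:, None, :]
            blocks = a.reshape(lv, n // size, size)
            u = blocks[:, :, :half]
            v = blocks[:, :, half:]
            m3 = m[:, :, None]
            # t = v*w mod m via reciprocal multiply + one correction
            q = (v.astype(np.float64) * wm - 0.5).astype(np.int64).view(_U64)
            t = v * w - q * m3
            t = np.where(t >= m3, t - m3, t)
            unew = u + t
            unew = np.where(unew >= m3, unew - m3, unew)
            vnew = np.where(u >= t, u - t, u - t + m3)
            blocks[:, :, :half] = unew
            blocks[:, :, half:] = vnew
            size *= 2
    return a


_BITREV_CACHE: dict[int, np.ndarray] = {}


def _bitrev_perm(n: int) -> np.ndarray:
    if n not in _BITREV_CACHE:
        bits = n.bit_length() - 1
        idx = np.arange(n)
        rev = np.zeros(n, dtype=np.int64)
        for b in range(bits):
            rev |= ((idx >> b) & 1) << (bits - 1 - b)
        _BITREV_CACHE[n] = rev
    return _BITREV_CACHE[n]


# ---------------------------------------------------------------------------
# Arithmetic on ring elements
# ---------------------------------------------------------------------------

def poly_add(a: RnsPoly, b: RnsPoly) -> RnsPoly:
    a._check_binary(b)
    m = a.chain.moduli[:a.level, None]
    return RnsPoly(a.chain, a.level, addmod(a.residues, b.residues, m), a.form)


def poly_sub(a: RnsPoly, b: RnsPoly) -> RnsPoly:
    a._check_binary(b)
    m = a.chain.moduli[:a.level, None]
    return RnsPoly(a.chain, a.level, submod(a.residues, b.residues, m), a.form)


def poly_neg(a: RnsPoly) -> RnsPoly:
    m = a.chain.moduli[:a.level, None]
    zero = np.zeros_like(a.residues)
    return RnsPoly(a.chain, a.level, submod(zero, a.residues, m), a.form)


def poly_mul(a: RnsPoly, b: RnsPoly) -> RnsPoly:
    """Pointwise product; both operands must be in evaluation form."""
    a._check_binary(b, need_form=EVAL)
    m = a.chain.moduli[:a.level, None]
    return RnsPoly(a.chain, a.level, mulmod(a.residues, b.residues, m), a.form)


def poly_scalar_mul(a: RnsPoly, scalars: np.ndarray) -> RnsPoly:
    """Multiply by a per-limb scalar (uint64 array of length ``level``)."""
    m = a.chain.moduli[:a.level, None]
    s = np.asarray(scalars, dtype=_U64)[:a.level, None]
    return RnsPoly(a.chain, a.level, mulmod(a.residues, s, m), a.form)


def drop_limb(a: RnsPoly, count: int) -> RnsPoly:
    """Remove the top ``count`` limbs (value preserved mod the remaining Q)."""
    if count < 0 or count >= a.level:
        raise ValueError("can drop at most level-1 limbs")
    if count == 0:
        return a.copy()
    lv = a.level - count
    return RnsPoly(a.chain, lv, a.residues[:lv].copy(), a.form)


def rescale_poly(a: RnsPoly) -> RnsPoly:
    """Divide by the top prime with rounding: round(x / q_l) mod Q_{l-1}.

    Implements the two-term RNS formula with the centered representative of
    the top limb: writing x = q_l t + x_l' with x_l' in (-q_l/2, q_l/2),
    the result t is the nearest integer to x / q_l (the primes are odd, so
    ties cannot occur).  Input and output are in evaluation form; the top
    limb is inverse-transformed (1 native NTT) and the derived term
    forward-transformed on the remaining limbs (l-1 native NTTs).
    """
    if a.form != EVAL:
        raise ValueError("rescale operates on evaluation form")
    if a.level < 2:
        raise ValueError("cannot rescale below one limb")
    chain = a.chain
    lv = a.level
    qinv, dres = chain.rescale_constants(lv)
    m = chain.moduli[:lv - 1, None]
    # term 1: x_i * q_l^-1 mod q_i, directly in evaluation form
    term1 = mulmod(a.residues[:lv - 1], qinv[:, None], m)
    # term 2: bring the top limb to coefficient form, scale, return to eval
    top_coeff = _limb_intt(chain, lv - 1, a.residues[lv - 1])  # in [0, q_l)
    xl = np.empty((lv - 1, chain.n), dtype=_U64)
    for i in range(lv - 1):
        xl[i] = np.mod(top_coeff, chain.moduli[i])
    term2_coeff = mulmod(xl, dres[:, None], m)
    # centered-representative correction: using x_l - q_l instead of x_l
    # wherever x_l > q_l/2 adds one to the quotient, turning the floor into
    # round-to-nearest
    ql = int(chain.primes[lv - 1])
    carry = (top_coeff > ql // 2).astype(_U64)[None, :]
    term2_coeff = addmod(term2_coeff, carry, m)
    term2 = ntt(RnsPoly(chain, lv - 1, term2_coeff, COEFF))
    out = addmod(term1, term2.residues, m)
    chain.counters.count_rescale()
    return RnsPoly(chain, lv - 1, out, EVAL)


def apply_automorphism(a: RnsPoly, g: int) -> RnsPoly:
    """a(x) -> a(x^g) for odd g, as a permutation in evaluation form."""
    if g % 2 == 0:
        raise ValueError("automorphism exponent must be odd")
    if a.form != EVAL:
        raise ValueError("automorphisms are applied in evaluation form")
    src = a.chain.automorphism_perm(g, EVAL)
    return RnsPoly(a.chain, a.level, np.ascontiguousarray(a.residues[:, src]),
                   EVAL)


def negacyclic_convolve_reference(a, b, q: int) -> list[int]:
    """O(n^2) schoolbook negacyclic convolution oracle (x^n = -1)."""
    a = [int(x) for x in a]
    b = [int(x) for x in b]
    n = len(a)
    out = [0] * n
    for i in range(n):
        for j in range(n):
            k = i + j
            if k < n:
                out[k] = (out[k] + a[i] * b[j]) % q
            else:
                out[k - n] = (out[k - n] - a[i] * b[j]) % q
    return out
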