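"""Binary containers and text manifests for ring elements and keys.

The binary container is a small header (ring dimension, level, exact scale
as a rational, encoding tag) followed by the limb-major little-endian 64-bit
word payload.  Payload bytes are exactly ``n_polys * level * n * 8`` for a
ciphertext and ``2 * level^2 * n * 8`` for a switch key, matching the
storage-accounting helpers; headers are excluded from all size accounting.

The modulus chain itself travels as a JSON manifest (n, p, ordered primes),
so a reader reconstructs bit-identical arithmetic from the primes actually
used rather than re-deriving them.
"""

from __future__ import annotations

import json
import struct
from fractions import Fraction
from typing import BinaryIO

import numpy as np

from .ckks import Ciphertext, Plaintext, SwitchKey
from .rns import ModulusChain, RnsPoly, COEFF, EVAL

_MAGIC = b"HEGWRNS1"
_REC_CIPHERTEXT = 1
_REC_PLAINTEXT = 2
_REC_SWITCHKEY = 3
_REC_SECRETKEY = 4

_FORM_CODE = {COEFF: 0, EVAL: 1}
_FORM_NAME = {v: k for k, v in _FORM_CODE.items()}


# ---------------------------------------------------------------------------
# Chain manifest
# ---------------------------------------------------------------------------

def save_chain(path: str, chain: ModulusChain) -> None:
    with open(path, "w") as fh:
        json.dump({"n": chain.n, "p": chain.p,
                   "primes": [int(q) for q in chain.primes]}, fh, indent=1)


def load_chain(path: str) -> ModulusChain:
    with open(path) as fh:
        doc = json.load(fh)
    return ModulusChain(int(doc["n"]), int(doc["p"]),
                        [int(q) for q in doc["primes"]])


# ---------------------------------------------------------------------------
# Low-level header/payload plumbing
# ---------------------------------------------------------------------------

def _write_bigint(fh: BinaryIO, value: int) -> None:
    if value < 0:
        raise ValueError("container rationals must be non-negative")
    raw = value.to_bytes((value.bit_length() + 7) // 8 or 1, "little")
    fh.write(struct.pack("<I", len(raw)))
    fh.write(raw)


def _read_bigint(fh: BinaryIO) -> int:
    (length,) = struct.unpack("<I", fh.read(4))
    return int.from_bytes(fh.read(length), "little")


def _write_tag(fh: BinaryIO, tag: str) -> None:
    raw = tag.encode("utf-8")
    fh.write(struct.pack("<H", len(raw)))
    fh.write(raw)


def _read_tag(fh: BinaryIO) -> str:
    (length,) = struct.unpack("<H", fh.read(2))
    return fh.read(length).decode("utf-8")


def _write_poly_payload(fh: BinaryIO, poly: RnsPoly) -> int:
    """Limb-major little-endian 64-bit words; returns payload bytes."""
    data = np.ascontiguousarray(poly.residues, dtype="<u8")
    fh.write(data.tobytes())
    return data.nbytes


def _read_poly_payload(fh: BinaryIO, chain: ModulusChain, level: int,
                       form: str) -> RnsPoly:
    count = level * chain.n
    raw = fh.read(count * 8)
    if len(raw) != count * 8:
        raise ValueError("truncated polynomial payload")
    res = np.frombuffer(raw, dtype="<u8").reshape(level, chain.n)
    return RnsPoly(chain, level, np.ascontiguousarray(res).astype(np.uint64),
                   form)


def _write_header(fh: BinaryIO, record: int, n: int, level: int,
                  n_polys: int, form: str, scale: Fraction,
                  tag: str) -> None:
    fh.write(_MAGIC)
    fh.write(struct.pack("<BIIIB", record, n, level, n_polys,
                         _FORM_CODE[form]))
    _write_bigint(fh, scale.numerator)
    _write_bigint(fh, scale.denominator)
    _write_tag(fh, tag)


def _read_header(fh: BinaryIO, expected_record: int) -> tuple:
    magic = fh.read(len(_MAGIC))
    if magic != _MAGIC:
        raise ValueError("not a hegwas binary container")
    record, n, level, n_polys, form = struct.unpack(
        "<BIIIB", fh.read(1 + 4 + 4 + 4 + 1))
    if record != expected_record:
        raise ValueError(f"container holds record type {record}, "
                         f"expected {expected_record}")
    num = _read_bigint(fh)
    den = _read_bigint(fh)
    tag = _read_tag(fh)
    return n, level, n_polys, _FORM_NAME[form], Fraction(num, den), tag


def _check_chain(chain: ModulusChain, n: int, level: int) -> None:
    if chain.n != n:
        raise ValueError(f"chain ring dimension {chain.n} != container {n}")
    if level > chain.L:
        raise ValueError("container level exceeds the chain length")


# ---------------------------------------------------------------------------
# Ciphertexts and plaintexts
# ---------------------------------------------------------------------------

def write_ciphertext(path: str, ct: Ciphertext) -> int:
    """Returns the payload byte count (header excluded)."""
    chain = ct.polys[0].chain
    payload = 0
    with open(path, "wb") as fh:
        _write_header(fh, _REC_CIPHERTEXT, chain.n, ct.level, ct.size,
                      ct.polys[0].form, Fraction(ct.scale), ct.tag)
        for poly in ct.polys:
            payload += _write_poly_payload(fh, poly)
    return payload


def read_ciphertext(path: str, chain: ModulusChain) -> Ciphertext:
    with open(path, "rb") as fh:
        n, level, n_polys, form, scale, tag = _read_header(
            fh, _REC_CIPHERTEXT)
        _check_chain(chain, n, level)
        polys = [_read_poly_payload(fh, chain, level, form)
                 for _ in range(n_polys)]
    return Ciphertext(polys, level, scale, tag)


def write_plaintext(path: str, pt: Plaintext) -> int:
    chain = pt.poly.chain
    with open(path, "wb") as fh:
        _write_header(fh, _REC_PLAINTEXT, chain.n, pt.level, 1,
                      pt.poly.form, Fraction(pt.scale), pt.tag)
        return _write_poly_payload(fh, pt.poly)


def read_plaintext(path: str, chain: ModulusChain) -> Plaintext:
    with open(path, "rb") as fh:
        n, level, _n_polys, form, scale, tag = _read_header(
            fh, _REC_PLAINTEXT)
        _check_chain(chain, n, level)
        poly = _read_poly_payload(fh, chain, level, form)
    return Plaintext(poly, level, scale, chain.n // 2, tag)


# ---------------------------------------------------------------------------
# Keys
# ---------------------------------------------------------------------------

def write_switchkey(path: str, swk: SwitchKey) -> int:
    chain = swk.pairs[0][0].chain
    level = swk.stored_level
    payload = 0
    with open(path, "wb") as fh:
        _write_header(fh, _REC_SWITCHKEY, chain.n, level, 2 * level,
                      EVAL, Fraction(1), "switch-key")
        for b, a in swk.pairs:
            payload += _write_poly_payload(fh, b)
            payload += _write_poly_payload(fh, a)
    return payload


def read_switchkey(path: str, chain: ModulusChain) -> SwitchKey:
    with open(path, "rb") as fh:
        n, level, n_polys, form, _scale, _tag = _read_header(
            fh, _REC_SWITCHKEY)
        _check_chain(chain, n, level)
        if n_polys != 2 * level:
            raise ValueError("switch key must hold one pair per limb")
        pairs = []
        for _ in range(level):
            b = _read_poly_payload(fh, chain, level, form)
            a = _read_poly_payload(fh, chain, level, form)
            pairs.append((b, a))
    return SwitchKey(pairs, level)


def write_secret_key(path: str, sk: RnsPoly) -> int:
    """Serialized as the pair (1, s) at the top level."""
    chain = sk.chain
    one = RnsPoly(chain, sk.level,
                  np.ones((sk.level, chain.n), dtype=np.uint64), sk.form)
    payload = 0
    with open(path, "wb") as fh:
        _write_header(fh, _REC_SECRETKEY, chain.n, sk.level, 2, sk.form,
                      Fraction(1), "secret-key")
        payload += _write_poly_payload(fh, one)
        payload += _write_poly_payload(fh, sk)
    return payload


def read_secret_key(path: str, chain: ModulusChain) -> RnsPoly:
    with open(path, "rb") as fh:
        n, level, _n_polys, form, _scale, _tag = _read_header(
            fh, _REC_SECRETKEY)
        _check_chain(chain, n, level)
        _read_poly_payload(fh, chain, level, form)   # the constant 1
        sk = _read_poly_payload(fh, chain, level, form)
    return sk
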