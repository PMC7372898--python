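"""Operation accounting shared by the ring layer and the scheme layer.

Counters are attached to a modulus chain / scheme context and incremented by
the primitives themselves, so complexity claims (native NTTs per key switch,
rotations per conversion, key switches in the SNP phase) can be asserted by
tests instead of trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class OpCounters:
    """Monotone counters for homomorphic-evaluation accounting.

    ``phase`` labels whether an operation happened before or after the first
    use of the encrypted SNP data ("pre-SNP" vs "SNP"); per-phase key-switch
    and rotation totals are kept separately so the SNP-phase claims can be
    checked in isolation.
    """

    native_ntts: int = 0
    relinearizations: int = 0
    rotations: int = 0
    rescales: int = 0
    simd_mults: int = 0
    mask_mults: int = 0
    phase: str = "pre-SNP"
    per_phase: dict = field(default_factory=dict)

    def _bump(self, name: str, amount: int = 1) -> None:
        setattr(self, name, getattr(self, name) + amount)
        key = (self.phase, name)
        self.per_phase[key] = self.per_phase.get(key, 0) + amount

    def count_ntt(self, amount: int) -> None:
        self._bump("native_ntts", amount)

    def count_relin(self) -> None:
        self._bump("relinearizations")

    def count_rotation(self) -> None:
        self._bump("rotations")

    def count_rescale(self) -> None:
        self._bump("rescales")

    def count_simd_mult(self) -> None:
        self._bump("simd_mults")

    def count_mask_mult(self) -> None:
        self._bump("mask_mults")

    def reset(self) -> None:
        """Zero every counter and return to the pre-SNP phase (for reusing a
        context, and thus its keys, across independent runs)."""
        self.native_ntts = 0
        self.relinearizations = 0
        self.rotations = 0
        self.rescales = 0
        self.simd_mults = 0
        self.mask_mults = 0
        self.phase = "pre-SNP"
        self.per_phase.clear()

    def set_phase(self, phase: str) -> None:
        if phase not in ("pre-SNP", "SNP"):
            raise ValueError(f"unknown phase label: {phase}")
        self.phase = phase

    def phase_total(self, phase: str, name: str) -> int:
        return self.per_phase.get((phase, name), 0)

    def snapshot(self) -> dict:
        return {
            "native_ntts": self.native_ntts,
            "relinearizations": self.relinearizations,
            "rotations": self.rotations,
            "rescales": self.rescales,
            "simd_mults": self.simd_mults,
            "mask_mults": self.mask_mults,
        }
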