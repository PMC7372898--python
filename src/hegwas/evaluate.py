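"""Accuracy evaluation and storage accounting.

Accuracy is summarized by the confusion table and F1 score at a significance
threshold, with the reference p-values defining truth.  Storage accounting
reproduces the full-profile ledger from pure payload arithmetic: every object
is a count of limb-major 64-bit containers whose sizes follow from the level
plan's limb assignments, with GiB = 2^30 bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gwas_encrypted import (FULL_PROFILE, SNP_MULT_DEPTH, X1_MULT_DEPTH,
                             LevelPlan)

GIB = float(1 << 30)
MIB = float(1 << 20)


# ---------------------------------------------------------------------------
# Confusion table / F1
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion summary of a pipeline's p-values against a reference.

    ``pairs`` keeps the paired (p_reference, p_pipeline) table so a p-p
    scatter can be exported; ``counters`` and ``sizes`` carry the run
    manifest's operation counts and byte ledger when one is supplied.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fpr: float
    tnr: float
    fnr: float
    f1: float
    pairs: np.ndarray
    counters: Optional[dict] = None
    sizes: Optional[dict] = None

    def __post_init__(self):
        for name in ("tpr", "fpr", "tnr", "fnr", "f1"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0, 1]: {v}")

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "confusion": {"tp": self.tp, "fp": self.fp,
                          "tn": self.tn, "fn": self.fn},
            "rates": {"tpr": self.tpr, "fpr": self.fpr,
                      "tnr": self.tnr, "fnr": self.fnr},
            "f1": self.f1,
            "pairs": [[float(a), float(b)] for a, b in self.pairs],
            "counters": self.counters,
            "sizes": self.sizes,
        }


def _rate(num: int, den: int) -> float:
    return num / den if den else 0.0


def confusion_f1(p_ref, p_test, threshold: float = 0.01,
                 counters: Optional[dict] = None,
                 sizes: Optional[dict] = None) -> EvalReport:
    """Confusion table and F1 of ``p_test`` against ``p_ref`` at ``threshold``.

    Significance means p < threshold; the reference defines truth.
    F1 = 2TP / (2TP + FP + FN), with the empty case (no positives on either
    side) scored as 1 -- the classifiers agree perfectly.
    """
    p_ref = np.asarray(p_ref, dtype=np.float64)
    p_test = np.asarray(p_test, dtype=np.float64)
    if p_ref.shape != p_test.shape or p_ref.ndim != 1:
        raise ValueError(
            f"p-value vectors must be 1-d of equal length, got shapes "
            f"{p_ref.shape} and {p_test.shape}")
    truth = p_ref < threshold
    called = p_test < threshold
    tp = int(np.sum(truth & called))
    fp = int(np.sum(~truth & called))
    tn = int(np.sum(~truth & ~called))
    fn = int(np.sum(truth & ~called))
    f1 = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    return EvalReport(
        threshold=threshold, tp=tp, fp=fp, tn=tn, fn=fn,
        tpr=_rate(tp, tp + fn), fpr=_rate(fp, fp + tn),
        tnr=_rate(tn, tn + fp), fnr=_rate(fn, fn + tp),
        f1=f1,
        pairs=np.column_stack([p_ref, p_test]),
        counters=counters, sizes=sizes)


# ---------------------------------------------------------------------------
# Storage ledger
# ---------------------------------------------------------------------------

def paper_plan() -> LevelPlan:
    """The full-profile level plan (L=17, p=50, n=2^15), constructed without
    materializing a 17-prime chain -- the ledger is pure arithmetic."""
    L = FULL_PROFILE["L"]
    return LevelPlan(
        profile="paper",
        L=L,
        scale_bits=FULL_PROFILE["p"],
        input_levels={"X": L, "Xt": L, "y": L,
                      "S": SNP_MULT_DEPTH + 1, "X1": X1_MULT_DEPTH + 1},
        rotation_keys={17: 16, 12: 13, 9: 12},
        notes={"n": str(FULL_PROFILE["n"])},
    )


def storage_report(plan: LevelPlan, dims: dict) -> dict:
    """Per-object payload byte counts for a cohort under a level plan.

    ``dims`` holds N (individuals), M (SNPs), K (non-intercept covariates)
    and n (ring dimension).  Objects:

    * S: one SIMD ciphertext per individual per slot-block of SNPs, at its
      planned limb count;
    * X1: N * (K+1) packed-integer ciphertexts at the X1 limb count;
    * X, Xt, y: one full-level ciphertext each (covariate phase);
    * rotation keys: the plan's per-level schedule of switch keys, each
      2 * level^2 * n * 8 payload bytes;
    * secret key: the (1, s) pair at the top level.

    All sizes are container payloads (headers excluded); GiB = 2^30.
    """
    N, M, K, n = (int(dims[key]) for key in ("N", "M", "K", "n"))
    slots = n // 2
    poly = lambda level: level * n * 8          # noqa: E731
    ct = lambda level, n_polys=2: n_polys * poly(level)  # noqa: E731
    swk = lambda level: 2 * level * poly(level)  # noqa: E731

    lev = plan.input_levels
    s_count = N * math.ceil(M / slots)
    x1_count = N * (K + 1)
    objects = {
        "S": {"count": s_count, "level": lev["S"],
              "bytes": s_count * ct(lev["S"])},
        "X1": {"count": x1_count, "level": lev["X1"],
               "bytes": x1_count * ct(lev["X1"])},
        "X": {"count": 1, "level": lev["X"], "bytes": ct(lev["X"])},
        "Xt": {"count": 1, "level": lev["Xt"], "bytes": ct(lev["Xt"])},
        "y": {"count": 1, "level": lev["y"], "bytes": ct(lev["y"])},
        "rotation_keys": {
            "schedule": {int(level): int(count)
                         for level, count in plan.rotation_keys.items()},
            "bytes": sum(count * swk(int(level))
                         for level, count in plan.rotation_keys.items()),
        },
        "secret_key": {"bytes": 2 * poly(plan.L)},
    }
    for obj in objects.values():
        obj["gib"] = obj["bytes"] / GIB
    objects["secret_key"]["mib"] = objects["secret_key"]["bytes"] / MIB

    report = {
        "profile": plan.profile,
        "dims": {"N": N, "M": M, "K": K, "n": n},
        "L": plan.L,
        "scale_bits": plan.scale_bits,
        "objects": objects,
        # Encrypting S at its first-use level instead of fresh, and counting
        # that level from the end of the circuit instead of the beginning
        # (7 limbs rather than the position-matched 9 = 8 + 1).
        "ratios": {
            "S_fresh_over_first_use": plan.L / lev["S"],
            "S_position_counted_over_depth_counted": 9 / lev["S"],
        },
        # Naive one-row-per-ciphertext matrix products would add a
        # log2(N)-level summation tree to the depth budget.
        "depth_increase_naive_rowsum_bits": math.ceil(math.log2(N)),
        "notes": {
            "convention": "GiB = 2^30 bytes; payloads only, headers excluded",
            "excluded": "relinearization-key and X/Xt/y composite figures "
                        "are not part of the ledger's cross-checks",
        },
    }
    return report
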