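"""Full-profile storage ledger from pure payload arithmetic.

Every object is a count of limb-major 64-bit containers whose sizes follow
from the level plan: the SNP matrix is encrypted with 7 CRT limbs (its
remaining multiplicative depth is 6), the packed-integer covariates with 6,
and the rotation keys are compressed down the chain as the circuit
descends.  GiB = 2^30 bytes.
"""

from hegwas.evaluate import paper_plan, storage_report

report = storage_report(paper_plan(), {"N": 245, "M": 10643, "K": 3,
                                       "n": 1 << 15})
o = report["objects"]
print(f"{'object':<14}{'count':>7}{'limbs':>7}{'GiB':>10}")
for name in ("S", "X1", "X", "Xt", "y"):
    obj = o[name]
    print(f"{name:<14}{obj['count']:>7}{obj['level']:>7}{obj['gib']:>10.4f}")
rk = o["rotation_keys"]
print(f"{'rotation keys':<14}{sum(rk['schedule'].values()):>7}"
      f"{'':>7}{rk['gib']:>10.4f}")
print(f"{'secret key':<14}{1:>7}{report['L']:>7}"
      f"{o['secret_key']['mib']:>9.1f}M")
r = report["ratios"]
print(f"\nS fresh / first-use level: {r['S_fresh_over_first_use']:.1f}x")
print(f"S position-counted / depth-counted: "
      f"{r['S_position_counted_over_depth_counted']:.1f}x")
print(f"depth increase a naive row-sum layout would add: "
      f"{report['depth_increase_naive_rowsum_bits']} levels")
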