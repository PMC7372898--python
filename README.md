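# hegwas

Semi-parallel logistic GWAS under an RNS variant of CKKS approximate
homomorphic encryption: per-SNP association statistics computed on
encrypted genotypes, covariates and phenotypes, with the client keeping the
secret key and performing only a final division and square root.

The package is a library first (`hegwas.*` modules), with narrative scripts
in `examples/` and a thin `hegwas` command-line wrapper. See
[docs/methods.md](docs/methods.md) for the science.

## Layout

```
src/hegwas/
  rns.py             negacyclic NTT / double-CRT polynomial arithmetic
  ckks.py            the leveled scheme: keys, mult, rotations, rescale,
                     noise bounds, storage accounting
  packing.py         slot layouts, folding reductions, encoding conversions
  gwas_plain.py      plaintext semi-parallel score + oracles + TSV I/O
  synthetic.py       seeded cohort simulation
  gwas_encrypted.py  the encrypted pipeline, level planner, run manifest
  evaluate.py        confusion/F1 report, storage ledger
  serialize.py       binary containers and the chain manifest
  cli.py             command-line surface
tests/               pytest suite (acceptance criteria in test_acceptance.py)
scripts/acceptance.py  recomputes the quantitative targets from scratch
examples/            runnable walkthroughs
```

## Worked example

```python
import numpy as np
from hegwas import (SimConfig, generate, fit_covariates, semi_parallel_z,
                    prepare_context, run_encrypted)

# 1. a seeded synthetic cohort: 16 individuals, 64 SNPs, 3 covariates
ds, causal = generate(SimConfig(N=16, M=64, K=3, n_causal=3, seed=0))

# 2. plaintext reference: one-step semi-parallel Wald scores for all SNPs
plain = semi_parallel_z(ds, fit_covariates(ds).theta)

# 3. the same circuit under encryption (toy profile: n=2^12, 45-bit primes;
#    key material depends only on the cohort shape, so one context serves
#    any dataset of this shape)
ctx = prepare_context(N=16, M=64, k=4, seed=0)
run = run_encrypted(ds, context=ctx)

print(np.max(np.abs(run.result.z - plain.z)))       # ~1e-6
print(run.manifest["snp_phase"])                     # 16 key switches,
                                                     # 0 rotations
```

The run manifest also records the level plan (the SNP matrix is encrypted
with 7 CRT limbs — 1 + its remaining multiplicative depth of 6), per-phase
operation counters, and payload byte counts for every encrypted object.

The same flow from the command line:

```sh
hegwas simulate --out cohort --n-individuals 16 --n-snps 64 --n-causal 3
hegwas run-plain --data cohort --out plain.tsv
hegwas run-encrypted --data cohort --out enc.tsv --manifest run.json
hegwas compare --reference plain.tsv --pipeline enc.tsv --out report.json
hegwas report-storage --profile paper      # full-profile storage ledger
```

`report-storage --profile paper` reproduces the full-profile ledger by pure
payload arithmetic (GiB = 2^30): SNP matrix 0.84 GiB at 7 limbs,
packed-integer covariates 2.87 GiB, rotation keys 3.65 GiB, secret key
8.5 MiB.

## Testing

```sh
python -m pytest            # full suite, including acceptance criteria
python scripts/acceptance.py --seed 0 --out acceptance.json
```

The acceptance script recomputes the quantitative targets from scratch:
SNP-phase key-switch count (16), the limb count assigned to the SNP matrix
by the full-profile planner (7), and the maximum low-order bits perturbed
by one rescale at n = 2^15 with 50-bit primes (<= 25).

## Notes

* The toy evaluation profile carries **no lattice security**; it runs the
  exact circuit at a small ring dimension for validation. The full profile
  (n = 2^15, p = 50, L = 17) is used for planning and storage arithmetic.
* All randomness is seeded and reproducible; results are independent of
  thread count.
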