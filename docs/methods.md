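# Methods

This document describes the science implemented by `hegwas`: a semi-parallel
one-step logistic genome-wide association scan evaluated under a residue
number system (RNS) variant of the CKKS approximate homomorphic encryption
scheme, so that a server can compute per-SNP association statistics without
ever seeing genotypes, covariates or phenotypes in the clear.

## 1. The statistical model

For each SNP `j` we test the coefficient `beta_j` in the logistic model

```
logit Pr(y_i = 1) = x_i' theta + s_ij beta_j
```

with `k = 4` covariate columns (intercept plus K = 3 covariates). A full
scan would fit M separate logistic regressions. The semi-parallel shortcut
fits the covariate-only model once and scores every SNP with a single
one-step Wald statistic, sharing all covariate-dependent algebra across
SNPs.

### Linearized fitting

Fitting under encryption must avoid data-dependent branching and division,
so two surrogates replace the textbook pieces:

* **Sigmoid**: the logistic function is replaced by the linear surrogate
  `sigma(x) ~ 1/2 + 0.15625 x`, accurate near 0 where standardized
  covariate scores concentrate. One gradient step from `theta = 0` with
  step size `alpha` gives the closed form
  `rho = 1/2 + 0.15625 alpha X X' (y - 1/2)`.
* **Working response**: the IRLS working response
  `zeta = logit(rho) + (y - rho) / (rho (1 - rho))` contains divisions, so
  it is replaced by its degree-8 Taylor expansion around `rho = 1/2` in
  `d = rho - 1/2`:

  ```
  zeta(rho, y) ~ (-2 + 4y) + (-8 + 16y) d^2 - 32/3 d^3 + (-32 + 64y) d^4
                 - 256/5 d^5 + (-128 + 256y) d^6 - 1536/7 d^7
                 + (-512 + 1024y) d^8
  ```

  The even coefficients depend on `y`; the odd ones (beyond the vanishing
  linear term) are constants. The test suite verifies every coefficient
  against symbolic differentiation.

### Division-free scoring

With weights `w = rho(1-rho)`, information matrix `H = X' W X`, and
Cramer's rule `H^{-1} = adj(H) / det(H)`, the one-step Wald score for SNP
`j` can be written without any division by data-dependent quantities:

```
S*  = det(H) S - X adj(H) X' W S          (projection of all SNPs at once)
num_j = (S*' W zeta*)_j,   den_j = (S*' W S*)_jj
z_j = num_j / (det(H) sqrt(den_j))
```

where `zeta* = det(H) zeta - X adj(H) X' W zeta`. The server computes
`num`, `den` and `det(H)` under encryption; the client performs the single
division and square root after decryption. The plaintext implementation of
this algebra agrees with a per-SNP oracle (explicit solve per SNP) to
1e-8, and its p-values reach F1 >= 0.95 at the 0.01 threshold against
fully converged per-SNP IRLS on a synthetic cohort of 245 individuals and
2000 SNPs.

For `k = 4`, `adj(H)` and `det(H)` are computed from shared 2x2 minors:
the Laplace determinant pairs complementary minors (binary product trees of
depth 2) and all sixteen cofactors reuse the same minors.

## 2. The encryption layer

### Ring arithmetic

Plaintexts live in `R_Q = Z_Q[x] / (x^n + 1)` with `Q = q_1 ... q_L` a
product of word-sized primes (`q_i ≡ 1 mod 2n`, alternating around `2^p`).
Polynomials are stored in double-CRT form: one `uint64` row per prime limb,
each row in the negacyclic NTT domain, so multiplication is elementwise.
Modular arithmetic uses an exact float-Barrett reduction (quotient via
`float64` reciprocal with +-1 correction), valid for moduli below `2^51`;
hot paths additionally have `numba` kernels with identical semantics, and
tests assert kernel == fallback bit-for-bit and NTT == schoolbook
negacyclic convolution against big-int arithmetic.

### CKKS operations

Complex vectors of `n/2` slots are embedded with scale `Delta = 2^p`.
The scheme provides SIMD addition/multiplication, slot rotations via
Galois automorphisms, relinearization, and rescaling:

* **Rescale** divides by the top prime with exact rounding: the two-term
  RNS formula with the centered representative of the top limb computes
  exactly `round(x / q_l)` per coefficient (primes are odd, so no ties),
  verified against a multiprecision oracle. Cost: `l` native NTTs per
  polynomial at level `l`. A single rescale at `n = 2^15`, `p = 50`
  perturbs at most ~20 of the 50 low-order bits of the scaled plaintext.
* **Key switching** uses single-digit CRT decomposition (window = one
  limb): `l` decompositions, each re-transformed on `l` limbs, i.e. `l^2`
  native NTTs per key switch — asserted by instrumentation, not assumed.
* **Lazy relinearization**: products grow ciphertexts beyond two
  polynomials (decryption evaluates `sum_t c_t s^t`); sums of such
  ciphertexts are relinearized once at the end. Keys for `s^2..s^4`.

### Noise policy

The additive key-switch noise `B_ksw ~ (8/sqrt(3)) n sigma q` of the
single-digit decomposition would swamp a ciphertext at base scale. Every
rotation and relinearization is therefore applied at a pre-rescale scale
(>= `Delta^2`) so the following rescale divides `B_ksw` down by `q_l`.
Rescale and encryption noise are *absolute* in ring units, so operand
scales are kept near `Delta` and operand *values* are shrunk instead: a
public protocol constant (512) divides `adj(H)`, `det(H)` and `w zeta*`
during operand preparation and cancels in `z`; the client multiplies the
raw decrypted numerator and denominator back up.

## 3. Packing and the encrypted circuit

Covariate-phase data use a packed-matrix encoding with one `k^2`-slot block
per individual: `X` row-cloned, `X'` element-cloned, `y` block-cloned.
Folding rotations (doubling trees) compute `X X' (y - 1/2)` and `H` with
`O(log N)` rotations — a naive one-row-per-ciphertext layout would add
`ceil(log2 N) = 8` levels of summation depth instead. The `k^2` entries of
`H` are extracted with hoisted rotations (one shared CRT decomposition) and
bit masks; adjoint and determinant are assembled from the shared minors
with lazy relinearization.

The SNP phase switches to a packed-integer encoding (one constant per
ciphertext) for `W`, `W zeta*` and `adj(H)`. Three conversion routines are
provided: (1) fill-clone + one mask per component, (2) a binary-tree split
costing `ceil(log2 N)` extra depth (it fails with a clean depth error on
the default chain), and (3) hoisted rotations with shared decomposition.
After conversion, the entire SNP-dependent computation
`S* = det(H) S - X_1(B_1(X_1'(W_1 S)))` and the score parts use only SIMD
products and binary-tree additions: **zero rotations and exactly k^2 = 16
relinearizations** — the only key switches that scale with the data phase,
asserted per run by the operation counters.

## 4. Level planning and storage

Levels are planned from the end of the circuit: each input is encrypted
with `1 +` (its remaining multiplicative depth) limbs. On the full profile
(`n = 2^15`, `p = 50`, `L = 17`): the SNP matrix has remaining depth 6,
hence **7 limbs** (2.4x smaller than fresh; 1.3x smaller than the 9 limbs
a position-counted assignment would give); the packed-integer covariates
enter one product later, hence 6 limbs. Rotation keys are compressed as
the circuit descends: 16 keys at 17 limbs, 13 at 12, 12 at 9.

Storage is pure payload arithmetic over the limb-major 64-bit container
(`n_polys * level * n * 8` bytes per ciphertext, `2 l^2 n * 8` per switch
key, GiB = 2^30): for N = 245, M = 10,643, K = 3 this gives S = 0.84 GiB,
X_1 = 2.87 GiB, rotation keys = 3.65 GiB, secret key 8.5 MiB.

## 5. Validation profile

The toy profile (`n = 2^12`, `p = 45`, `L = 22`) carries no lattice
security; it exists to run the *exact* circuit fast. On it, decrypted
z-scores agree with the plaintext semi-parallel reference to ~1e-6
(acceptance threshold: three decimal places) across seeded cohorts, with
identical degeneracy flags. All randomness is seeded; identical seeds give
byte-identical datasets, keys and ciphertexts.
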