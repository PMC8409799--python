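# Methods

## Model

Imputation is cast as one independent 3-class classification problem per
target SNP.  For target `t`, the feature vector is the one-hot encoding of
the `k = 10` tag SNPs with the highest plug-in mutual information with `t`
(ties broken by ascending genomic position, so selection is deterministic).
The classifier is linear with no activation: class scores are `s = Wx + b`
with `W ∈ R^{3×3k}`, `b ∈ R^3`, both constrained non-negative.  The
predicted genotype is the class of the largest raw score; the normalization
`p_k = s_k / Σ_l s_l` is rank-preserving, so it is computed only when ROC
curves are needed, never for prediction — this is what lets the encrypted
server skip division entirely.

One-hot convention: genotype `g ∈ {0,1,2}` sets bit `2−g`, i.e. `[0,0,1]`,
`[0,1,0]`, `[1,0,0]`.  Score position `j` therefore votes for genotype
`2−j`; argmax ties resolve to the lowest position (the highest genotype), a
deterministic rule applied identically in the plaintext and encrypted paths.

### Training

Adam on softmax cross-entropy, mini-batches of 32, initial learning rate
8e-4 with no decay, halved after 3 consecutive non-improving epochs down to
a floor of 1e-5, early stop after 10 further non-improving epochs at the
floor, at most 200 epochs.  After every update both `W` and `b` are
projected to `≥ 0` (per-update clipping; the timing of the projection is a
design choice — per-update keeps the iterates feasible at all times).
Parameters are initialized uniformly in `[0, 0.01]` from the training seed;
training is fully deterministic given that seed.  A non-finite loss aborts
with diagnostics; a single-class (monomorphic) target yields a bias-only
model that predicts the constant class.

### Integer scaling

Weights are scaled by `2^scale` (`scale = 8`) and rounded; every scaled
value must fit `weight_bits = 8` bits.  Mini-batch training can push weights
past 1.0, which would overflow 8 bits, so the training pipeline first
divides each target's `(W, b)` by a common positive factor chosen so the
largest scaled integer is exactly `2^8 − 1`.  A common positive rescaling of
one target's scores changes neither the argmax nor the per-sample normalized
probabilities, so accuracy and AUC are untouched; `scale_to_int` itself
still raises on overflow so a hand-built model cannot silently corrupt slot
arithmetic.  The fraction of predictions where the integer and float argmax
differ is measured and stored on every model (typically ≤ 0.2%); exact
agreement is not promised, only measured.

## Paillier implementation

Textbook Paillier over Python's arbitrary-precision integers: `N = pq` with
`p ≠ q` random probable primes of `key_bits/2` bits (Miller–Rabin, 40
rounds, top two bits forced so `N` has exactly `key_bits` bits), `λ =
lcm(p−1, q−1)`, `μ = L(g^λ mod N²)^{−1} mod N`, `L(x) = (x−1)/N` with an
exact-divisibility check (failure means a corrupted ciphertext or wrong
key).  The generator defaults to `g = N + 1`, for which `g^m = 1 + mN mod
N²` is closed-form; a general `g` is supported through a table of
`g^(2^i) mod N²` so that `g^m` is a product of table entries selected by the
bits of `m` — both paths are exercised in the tests.

Encryption randomness comes from a zero cache: a pool (default 64) of
precomputed `r^N mod N²` values.  A fresh zero is the product of two
distinct pool members — an `N`-th residue, hence still an encryption of
zero — and the product replaces one of the members, so the pool
re-randomizes itself on every draw and returned zeros do not repeat (tested:
10⁴ encryptions of one message on a 64-bit key, no collision).  This removes
every exponentiation from the encryption path.

Decryption uses the standard CRT split (one half-size exponentiation modulo
`p²` and one modulo `q²`, recombined), which is algebraically identical to
the textbook formula and about 3× faster in pure Python; the textbook path
is retained and cross-checked.  Homomorphic scalar multiplication is
shift-and-add over the bits of the scalar (equivalently `c^k mod N²`);
negative scalars are rejected — the non-negativity constraint upstream is
what makes a negative encoding unnecessary.

Key-handling policy: key sizes below 1024 bits require an explicit
`insecure_toy_mode` flag; a seeded RNG is honored when explicitly injected
(reproducible runs) but marks the key pair as seeded and the CLI logs a
warning.  The server API accepts a `PublicKey` only and rejects any object
that could carry private material.

## Slot packing

Slot width is `weight_bits + ⌈log₂ n⌉` for `n` addends.  The default layout
counts the bias as one extra addend (`n = 3k + 1 = 31`), which for the
10-tag model still gives 13 bits, hence 236 individuals per 3072-bit
ciphertext; both the with-bias and without-bias conventions are exposed.
Slots are least-significant-first, making pack/unpack pure shift/mask loops.
Before any homomorphic work the server recomputes each model's worst-case
accumulated slot value (per tag block, the largest weight — inputs are
one-hot — summed over blocks, plus the bias) and refuses layouts it could
overflow.  A client batch that does not fill the last ciphertext pads it
with zero slots, dropped on unpack.  The bias is added server-side as
`c · g^(packed bias)`; adding a fresh encryption of the packed bias instead
decrypts identically and is available through the same operation set.

## Synthetic data generator

Per block, a pool of founder binary haplotypes (default 4) is drawn; each
individual samples two founders uniformly with replacement and flips each
inherited allele with the per-site mutation rate (default 0.01); the
genotype is the allele sum.  This is the simplest mechanism that produces
within-block LD and zero cross-block LD, which is exactly what MI-based tag
selection and the imputation premise require.  The mutation rate is the
learnability dial: within-block tag–target MI decreases monotonically in it
(tested at three settings).

Default study conditions: 2,000 individuals (1,500 train / 500 test), 13
blocks × 10 SNPs, 60/40 tag/target split per block (78 tags, 52 targets),
`k = 10`, `scale = 8`, 3072-bit key.

What the generator does **not** emulate: recombination gradients and LD
decay within blocks, demographic structure, allele-frequency spectra from
real site-frequency spectra, phasing ambiguity beyond unordered founder
pairs, genotyping error models, or missing data.  Consequently, passing
tests demonstrate the *mechanics* — selection finds the informative tags,
training converges under the constraints, the encrypted pipeline is exact,
metrics behave — but measured accuracies say nothing quantitative about real
cohorts; real-panel accuracy depends on LD structure the simulation only
sketches.

## Evaluation and the chance-level control

Accuracy is fraction-correct over all (individual, target) pairs;
macro-average accuracy is the unweighted mean of per-variant accuracies
(when individual counts differ per variant, the unweighted mean over
variants is used).  ROC analysis is one-vs-rest per genotype class;
micro-AUC pools all (prediction, class) pairs into one binary ROC
(trapezoidal integration, midpoint tie convention — it equals the
Mann–Whitney pairwise statistic, which the tests verify by brute force).
Micro-AUC is invariant under monotone score transforms, so raw integer
scores and normalized probabilities give the same value.

The no-signal control trains on labels drawn **uniformly at random** rather
than on permuted labels.  Permutation preserves each target's class priors,
and a model trained on permuted labels still learns those priors;
micro-averaged one-vs-rest AUC rewards prior information under class
imbalance (a prior-only scorer exceeds 0.5 whenever priors are non-uniform,
and monomorphic targets are unchanged by permutation entirely).  Measured on
the default panel, a permutation control sits near 0.78 while carrying no
tag–target signal; the uniform-relabel control, which destroys both the LD
signal and the prior information, sits at 0.50 and is the appropriate
chance reference for this metric.

## Numerical choices and degenerate inputs

- MI: plug-in estimator, natural log, no bias correction — only the ranking
  matters.  Zero joint cells contribute zero.
- All-zero score vectors normalize to the uniform distribution (they arise
  only when every weight and bias of a class triple is zero).
- Missing genotypes are rejected everywhere (training, encryption, VCF
  parsing); the pipeline assumes complete panels.
- Fold assignment in cross-validation is a seeded permutation split; folds
  partition the individuals exactly.
- Thread-level parallelism partitions work by target; the per-ciphertext
  accumulation order is fixed, so decrypted results (and in this
  implementation even the ciphertexts) are independent of the thread count.

## Problem sizes used by the test suite

The full-scale exactness check runs the complete 500-individual test set at
capacity batching (236 per ciphertext) and on a 237-individual query (which
spills into a 236 + 1 split), with 1 and 4 threads.  The batch-size-1
configuration multiplies the number of decryptions by the batch count
(500 × 52 × 3 ciphertexts), so it is verified on a 16-individual ×
10-target slice — per-slot arithmetic is identical for every batch size, so
the slice exercises the same code path at 1/300th of the decryption cost.
Bulk cryptographic sampling (1,000 random messages) runs on the 1024-bit
key, with smaller samples plus all identity checks repeated on the 3072-bit
key.

## Known limitations

- Pure-Python big-integer arithmetic: a 3072-bit decryption costs ~0.15 s,
  so throughput is bounded by decryptions (mitigated by packing, CRT, and
  threads at the protocol level, not by a faster multiplication kernel).
- Honest-but-curious threat model only: no protection against a server that
  returns wrong results, and no threshold or distributed decryption.
- Paillier cannot multiply two ciphertexts, so only linear models are
  servable; non-linear models would need a different encryption scheme.
- Training itself is plaintext: the reference panel is assumed public.
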