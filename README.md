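# cryptimpute

Privacy-preserving genotype imputation with the Paillier cryptosystem.

## The problem

Genotype imputation predicts the genotypes of unobserved *target* SNPs from a
set of observed *tag* SNPs, exploiting linkage disequilibrium within
haplotype blocks.  Imputation is routinely outsourced — but a genome is
uniquely identifying and cannot be revoked, so sending tag genotypes to a
cloud service in plaintext is a serious privacy exposure even when the
service computes honestly.

`cryptimpute` lets an honest-but-curious server impute genotypes **without
ever seeing them**.  The model is trained on a plaintext reference panel;
inference runs entirely on encrypted data:

1. **Per-target linear models.**  For each target SNP, the top 10 tag SNPs
   by mutual information `I(X;Y) = Σ p(x,y) log[p(x,y)/(p(x)p(y))]` are
   one-hot encoded (genotypes 0/1/2 → `[0,0,1]`, `[0,1,0]`, `[1,0,0]`) and
   mapped to three class scores `s = Wx + b`.  Training (Adam, softmax
   cross-entropy) clips `W, b ≥ 0` after every update and the weights are
   then scaled by `2^8` and rounded to 8-bit non-negative integers — so the
   encrypted pipeline needs neither floating point nor negative numbers.
   The prediction is `argmax s`; normalizing scores into probabilities is
   rank-preserving and only ever needed for ROC curves.
2. **Paillier homomorphic encryption.**  `E(m, r) = g^m · r^N mod N²` with a
   3072-bit `N` (128-bit security).  Multiplying ciphertexts adds plaintexts,
   so the server can compute `E(Wx + b)` from `E(x)` and its plaintext
   integer weights — while the private key `(λ, μ)` never leaves the client.
3. **Slot packing.**  A score of a 10-tag model fits in
   `8 + ⌈log₂ 30⌉ = 13` bits, so one 3072-bit plaintext packs
   `⌊3072/13⌋ = 236` individuals.  One homomorphic operation — and crucially
   one expensive decryption — advances 236 individuals at once.  Encryption
   itself is accelerated with precomputed zero ciphertexts and (for general
   generators) precomputed powers `g^(2^i)`.

Because every step after integer scaling is exact integer arithmetic, the
encrypted predictions are **bit-identical** to running the integer model in
plaintext — the package tests this end to end.

## Worked example

`examples/04_encrypted_imputation.py` trains on 250 synthetic individuals and
imputes 52 target SNPs for 50 held-out individuals under a 1024-bit demo key:

```
client: 50 individuals -> 13-bit slots, 78 per ciphertext, 216 ciphertexts sent
server: computed 156 encrypted score ciphertexts without the private key
encrypted == plaintext scores:      True
encrypted == plaintext predictions: 100.0%
imputation quality: accuracy 0.8531, micro-AUC 0.9516
```

Reading the numbers: the client encrypted the one-hot bits of the 72 tag
SNPs the models actually use (3 positions × 72 tags × 1 batch = 216
ciphertexts); the server returned 52 targets × 3 classes = 156 packed score
ciphertexts; decrypting and unpacking them reproduces the plaintext integer
scores exactly, and the genotype calls are right for 85% of
(individual, target) pairs with a pooled one-vs-rest AUC of 0.95 — the
privacy costs nothing in accuracy relative to the same model in plaintext.

The other examples cover the Paillier primitives (`01`), slot packing
(`02`), training and evaluation (`03`), and the file-based CLI workflow
(`05`).  The CLI mirrors the deployment roles:

```bash
cryptimpute keygen | simulate | train | encrypt | impute | decrypt | evaluate | e2e
```

`impute` (the server role) refuses to run if handed a private-key file.

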