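"""Paillier basics: key generation, encryption, and homomorphic arithmetic.

Generates a small (insecure, demo-only) key pair, encrypts two genotype-
scale integers, and shows that multiplying ciphertexts adds plaintexts and
that exponentiating by a plaintext scalar multiplies them — the two
operations the encrypted imputation server relies on.
"""

from random import Random

from cryptimpute import paillier as pa

kp = pa.keygen(256, rng=Random(0), insecure_toy_mode=True)
print(f"key: N has {kp.public.N.bit_length()} bits, g = N+1 (demo size; "
      "production uses 3072 bits)")

a, b, k = 17, 25, 6
ca, cb = kp.encrypt(a), kp.encrypt(b)

added = pa.hom_add(ca, cb, kp.public)
scaled = pa.hom_scalar_mult(ca, k, kp.public)
shifted = pa.hom_add_plaintext(cb, 100, kp.public)

print(f"D(E({a}) * E({b}))      = {kp.decrypt(added)}   (ciphertext product adds plaintexts)")
print(f"D(E({a})^{k})           = {kp.decrypt(scaled)}  (ciphertext power scales the plaintext)")
print(f"D(E({b}) * g^100)      = {kp.decrypt(shifted)}  (plaintext constant added for free)")

c1, c2 = kp.encrypt(a), kp.encrypt(a)
print(f"two encryptions of {a} differ: {c1.value != c2.value} "
      "(probabilistic encryption via the zero cache)")
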