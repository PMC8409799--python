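"""The full privacy-preserving round trip: encrypt, impute blind, decrypt.

The client packs and encrypts only the tag SNPs the models need; the server
(public key only — it cannot decrypt anything) computes the linear scores
homomorphically; the client decrypts one ciphertext per (target, class,
batch) and takes the argmax.  The encrypted predictions are bit-exact equal
to running the integer model in plaintext.

A 1024-bit key keeps this demo fast; the production default is 3072 bits.
"""

from random import Random

import numpy as np

import cryptimpute as ci
from cryptimpute import paillier as pa

kp = pa.keygen(1024, rng=Random(7))
panel = ci.simulate_panel(ci.SimConfig(n_individuals=300, seed=7))
train, test = panel.split(250)
model = ci.train_imputation_model(
    train, ci.ModelConfig(key_bits=1024, train=ci.TrainConfig(seed=7)))

query = ci.client_encrypt(test.tags_only(), model, kp)
layout = query.layout
print(f"client: {test.n_individuals} individuals -> {layout.slot_bits}-bit slots, "
      f"{layout.slot_count} per ciphertext, "
      f"{sum(len(v) for v in query.bits.values())} ciphertexts sent")

result = ci.server_impute(query, model, kp.public, threads=2)
n_out = sum(len(b) for pc in result.scores.values() for b in pc)
print(f"server: computed {n_out} encrypted score ciphertexts without the private key")

pred = ci.client_decrypt_predict(result, kp, model,
                                 individual_ids=test.individual_ids)
plain_geno, plain_scores = model.predict(test.tags_only())
print(f"encrypted == plaintext scores:      {bool((pred.scores == plain_scores).all())}")
print(f"encrypted == plaintext predictions: {float(np.mean(pred.genotypes == plain_geno)):.1%}")

truth = np.column_stack([test.column(t) for t in model.target_ids])
report = ci.evaluate(pred.genotypes, pred.scores.astype(float), truth,
                     target_ids=model.target_ids)
print(f"imputation quality: accuracy {report.accuracy:.4f}, "
      f"micro-AUC {report.micro_auc:.4f}")
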