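"""Encrypted inference protocol: exactness, batching, blindness, integrity."""

import numpy as np
import pandas as pd
import pytest

import cryptimpute as ci
from cryptimpute.genotypes import GenotypeError, GenotypeMatrix
from cryptimpute.inference import (
    ProtocolError,
    client_decrypt_predict,
    client_encrypt,
    model_layout,
    server_impute,
)
from cryptimpute.model import CLASS_ORDER, ImputationModel, ModelConfig, TargetModel, TrainConfig


def tiny_model(W_int_row, b_int_val, key_bits=256):
    """One target, one tag; the same weight row for all three classes except
    as overridden — enough to drive the packed arithmetic directly."""
    W_int = np.tile(np.asarray(W_int_row, dtype=np.int64), (3, 1))
    b_int = np.full(3, b_int_val, dtype=np.int64)
    tm = TargetModel(target_id="tgt", selected_tags=["tag"],
                     W=W_int / 256.0, b=b_int / 256.0, scale=8,
                     W_int=W_int, b_int=b_int)
    cfg = ModelConfig(k_tags=1, scale=8, weight_bits=8, key_bits=key_bits,
                      train=TrainConfig())
    return ImputationModel(targets=[tm], config=cfg)


def panel_from_column(genos):
    meta = pd.DataFrame({"id": ["tag"], "chrom": ["1"], "pos": [100],
                         "role": ["tag"]})
    return GenotypeMatrix(np.asarray(genos, dtype=np.int8)[:, None], meta)


class TestPackedLinearAlgebra:
    def test_two_individual_worked_example(self, kp256):
        """W_int = [2,3,0], b_int = 1: genotype 2 -> one-hot [1,0,0] -> 2+1=3;
        genotype 1 -> [0,1,0] -> 3+1=4."""
        model = tiny_model([2, 3, 0], 1)
        panel = panel_from_column([2, 1])
        q = client_encrypt(panel, model, kp256)
        res = server_impute(q, model, kp256.public)
        pred = client_decrypt_predict(res, kp256, model)
        assert pred.scores[:, 0, 0].tolist() == [3, 4]

    def test_all_zero_weights_leave_bias(self, kp256):
        model = tiny_model([0, 0, 0], 5)
        panel = panel_from_column([0, 1, 2, 1])
        q = client_encrypt(panel, model, kp256)
        res = server_impute(q, model, kp256.public)
        pred = client_decrypt_predict(res, kp256, model)
        assert (pred.scores == 5).all()

    def test_zero_weight_skipping_is_a_no_op(self, kp256):
        model = tiny_model([7, 0, 2], 1)
        panel = panel_from_column([0, 2, 1, 1, 0])
        q = client_encrypt(panel, model, kp256)
        with_skip = client_decrypt_predict(
            server_impute(q, model, kp256.public, skip_zero_weights=True),
            kp256, model)
        without = client_decrypt_predict(
            server_impute(q, model, kp256.public, skip_zero_weights=False),
            kp256, model)
        assert (with_skip.scores == without.scores).all()

    def test_query_ciphertexts_round_trip_bit_columns(self, kp256):
        from cryptimpute.packing import unpack
        from cryptimpute.model import one_hot_matrix
        model = tiny_model([1, 1, 1], 0)
        genos = [0, 1, 2, 2, 0, 1, 1]
        panel = panel_from_column(genos)
        q = client_encrypt(panel, model, kp256, batch_size=3)
        onehot = one_hot_matrix(np.asarray(genos))
        for pos in range(3):
            recovered = []
            offset = 0
            for bi, bsz in enumerate(q.batch_sizes):
                plain = kp256.decrypt(q.bits[("tag", pos)][bi])
                recovered += unpack(plain, q.layout, bsz)
                offset += bsz
            assert recovered == onehot[:, pos].tolist()


class TestEndToEndExactness:
    def _trained_setup(self, kp, seed=0, n=60, n_test=20):
        panel = ci.simulate_panel(ci.SimConfig(
            n_individuals=n, n_blocks=3, snps_per_block=5, seed=seed))
        train, test = panel.split(n - n_test)
        cfg = ModelConfig(k_tags=3, key_bits=kp.public.key_bits,
                          train=TrainConfig(seed=seed, epochs=60))
        model = ci.train_imputation_model(train, cfg)
        return model, test

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_encrypted_equals_plaintext_integer_inference(self, kp256, seed):
        model, test = self._trained_setup(kp256, seed=seed)
        q = client_encrypt(test.tags_only(), model, kp256)
        res = server_impute(q, model, kp256.public)
        pred = client_decrypt_predict(res, kp256, model)
        plain_geno, plain_scores = model.predict(test.tags_only())
        assert (pred.scores == plain_scores).all()
        assert (pred.genotypes == plain_geno).all()

    def test_batch_invariance(self, kp256):
        model, test = self._trained_setup(kp256, seed=3)
        baselines = None
        capacity = model_layout(model, kp256.public.key_bits).slot_count
        for bs in (1, 3, 7, capacity):
            q = client_encrypt(test.tags_only(), model, kp256, batch_size=bs)
            res = server_impute(q, model, kp256.public)
            pred = client_decrypt_predict(res, kp256, model)
            if baselines is None:
                baselines = pred.scores
            else:
                assert (pred.scores == baselines).all()

    def test_thread_invariance(self, kp256):
        model, test = self._trained_setup(kp256, seed=4)
        q = client_encrypt(test.tags_only(), model, kp256)
        single = client_decrypt_predict(
            server_impute(q, model, kp256.public, threads=1), kp256, model)
        multi = client_decrypt_predict(
            server_impute(q, model, kp256.public, threads=4), kp256, model)
        assert (single.scores == multi.scores).all()


class TestPredictionRules:
    def test_argmax_and_tie_rules(self, kp256):
        # class scores are driven through the real packed pipeline by a
        # model whose per-class weights are the desired score patterns
        W_int = np.zeros((3, 3), dtype=np.int64)
        W_int[:, 0] = [5, 9, 2]   # genotype 2 input -> scores (5, 9, 2)
        W_int[:, 1] = [4, 4, 1]   # genotype 1 input -> tie (4, 4, 1)
        tm = TargetModel(target_id="tgt", selected_tags=["tag"],
                         W=W_int / 256.0, b=np.zeros(3), scale=8,
                         W_int=W_int, b_int=np.zeros(3, dtype=np.int64))
        model = ImputationModel(targets=[tm], config=ModelConfig(
            k_tags=1, key_bits=256, train=TrainConfig()))
        panel = panel_from_column([2, 1])
        q = client_encrypt(panel, model, kp256)
        pred = client_decrypt_predict(
            server_impute(q, model, kp256.public), kp256, model)
        # scores (5,9,2): argmax position 1 -> genotype CLASS_ORDER[1] = 1
        assert pred.genotypes[0, 0] == 1
        # tie (4,4,1): lowest position wins -> genotype CLASS_ORDER[0] = 2
        assert pred.genotypes[1, 0] == 2
        assert CLASS_ORDER == (2, 1, 0)


class TestProtocolContracts:
    def test_server_rejects_keypair(self, kp256):
        model = tiny_model([1, 0, 0], 0)
        q = client_encrypt(panel_from_column([1]), model, kp256)
        with pytest.raises(ProtocolError):
            server_impute(q, model, kp256)  # KeyPair, not PublicKey

    def test_key_fingerprint_checked(self, kp256, kp64):
        model = tiny_model([1, 0, 0], 0, key_bits=64)
        q = client_encrypt(panel_from_column([1]), model, kp64)
        with pytest.raises(ProtocolError):
            server_impute(q, model, kp256.public)

    def test_missing_tag_snps_listed(self, kp256):
        model = tiny_model([1, 0, 0], 0)
        meta = pd.DataFrame({"id": ["other"], "chrom": ["1"], "pos": [1],
                             "role": ["tag"]})
        panel = GenotypeMatrix(np.zeros((2, 1), dtype=np.int8), meta)
        with pytest.raises(GenotypeError, match="tag"):
            client_encrypt(panel, model, kp256)

    def test_slot_overflow_refused_up_front(self, kp256):
        # worst-case slot value 600 + 600 exceeds the 10-bit slot budget (1024)
        model = tiny_model([600, 600, 600], 600)
        q = client_encrypt(panel_from_column([1, 2]), model, kp256)
        with pytest.raises(ProtocolError, match="slot"):
            server_impute(q, model, kp256.public)

    def test_batch_size_bounds(self, kp256):
        model = tiny_model([1, 0, 0], 0)
        with pytest.raises(ProtocolError):
            client_encrypt(panel_from_column([1]), model, kp256, batch_size=0)

    def test_decrypt_requires_private_key(self, kp256):
        model = tiny_model([1, 0, 0], 0)
        q = client_encrypt(panel_from_column([1]), model, kp256)
        res = server_impute(q, model, kp256.public)
        from cryptimpute.paillier import MissingPrivateKeyError
        with pytest.raises(MissingPrivateKeyError):
            client_decrypt_predict(res, kp256.public_only(), model)
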