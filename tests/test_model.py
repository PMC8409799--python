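"""Imputation models: encoding, MI selection, constrained training, scaling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import mutual_info_score

import cryptimpute as ci
from cryptimpute.genotypes import GenotypeError, GenotypeMatrix
from cryptimpute.model import (
    ModelConfig,
    ScaleOverflowError,
    TargetModel,
    TrainConfig,
    TrainingError,
    class_probabilities,
    cross_validate,
    genotype_from_position,
    mutual_information,
    one_hot,
    one_hot_matrix,
    rescale_to_fit,
    scale_to_int,
    select_top_k,
    train_target_model,
)


def brute_force_mi(x, y):
    """Direct summation over the empirical joint table (independent oracle)."""
    n = len(x)
    total = 0.0
    for a in set(x):
        for b in set(y):
            pxy = sum(1 for xi, yi in zip(x, y) if xi == a and yi == b) / n
            if pxy == 0:
                continue
            px = sum(1 for xi in x if xi == a) / n
            py = sum(1 for yi in y if yi == b) / n
            total += pxy * math.log(pxy / (px * py))
    return total


class TestOneHot:
    @pytest.mark.parametrize("g,expected", [(0, [0, 0, 1]), (1, [0, 1, 0]), (2, [1, 0, 0])])
    def test_mapping(self, g, expected):
        assert one_hot(g).tolist() == expected

    def test_inverse(self):
        for g in (0, 1, 2):
            pos = int(np.argmax(one_hot(g)))
            assert genotype_from_position(pos) == g

    def test_invalid_genotype(self):
        with pytest.raises(GenotypeError):
            one_hot(3)

    def test_matrix_layout(self):
        X = one_hot_matrix(np.array([[0, 2], [1, 1]]))
        assert X.tolist() == [[0, 0, 1, 1, 0, 0], [0, 1, 0, 0, 1, 0]]


class TestMutualInformation:
    def test_constant_column_gives_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 500)
        assert mutual_information(x, np.zeros(500, dtype=int)) == pytest.approx(0.0)

    def test_identical_uniform_binary_gives_ln2(self):
        x = np.array([0, 1] * 50)
        assert mutual_information(x, x) == pytest.approx(math.log(2), abs=1e-12)

    def test_matches_brute_force_oracle_on_2x2_table(self):
        # joint counts [[2,1],[1,2]] over 6 samples
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        assert mutual_information(x, y) == pytest.approx(brute_force_mi(x, y), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_nonnegativity_and_sklearn_agreement(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, 60)
        y = rng.integers(0, 3, 60)
        mi_xy = mutual_information(x, y)
        assert mi_xy == pytest.approx(mutual_information(y, x), abs=1e-12)
        assert mi_xy >= -1e-12
        assert mi_xy == pytest.approx(mutual_info_score(x, y), abs=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(GenotypeError):
            mutual_information(np.zeros(5, dtype=int), np.zeros(6, dtype=int))


class TestSelection:
    positions = {"a": 100, "b": 200, "c": 300}

    def test_perfect_copy_ranks_first(self):
        rng = np.random.default_rng(1)
        target = rng.integers(0, 3, 200)
        noise = rng.integers(0, 3, 200)
        scores = pd.DataFrame(
            {"t": [mutual_information(target, target),
                   mutual_information(noise, target),
                   mutual_information(rng.integers(0, 3, 200), target)]},
            index=["a", "b", "c"])
        assert select_top_k(scores, "t", 1, self.positions) == ["a"]

    def test_all_tags_when_k_equals_count(self):
        scores = pd.DataFrame({"t": [0.1, 0.3, 0.2]}, index=["a", "b", "c"])
        assert select_top_k(scores, "t", 3, self.positions) == ["b", "c", "a"]

    def test_tie_breaks_by_position(self):
        scores = pd.DataFrame({"t": [0.2, 0.2, 0.5]}, index=["a", "b", "c"])
        assert select_top_k(scores, "t", 2, self.positions) == ["c", "a"]

    def test_invalid_k(self):
        scores = pd.DataFrame({"t": [0.2]}, index=["a"])
        with pytest.raises(ValueError):
            select_top_k(scores, "t", 0, self.positions)


class TestTraining:
    def _separable_data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        tag = rng.integers(0, 3, n)
        X = one_hot_matrix(np.column_stack([tag, rng.integers(0, 3, n)]))
        Y = one_hot_matrix(tag)  # target duplicates the first tag
        return X, Y, tag

    def test_separable_problem_fits_perfectly(self):
        X, Y, tag = self._separable_data()
        tm = train_target_model(X, Y, TrainConfig(seed=0))
        pred = tm.predict(X, integer=False)
        assert np.mean(pred == tag) == 1.0

    def test_parameters_stay_nonnegative(self):
        X, Y, _ = self._separable_data(seed=3)
        tm = train_target_model(X, Y, TrainConfig(seed=1))
        assert (tm.W >= 0).all() and (tm.b >= 0).all()

    def test_constant_target_yields_majority_model(self):
        rng = np.random.default_rng(2)
        X = one_hot_matrix(rng.integers(0, 3, (50, 2)))
        Y = one_hot_matrix(np.full(50, 2))
        tm = train_target_model(X, Y)
        assert (tm.predict(X, integer=False) == 2).all()

    def test_too_few_rows_rejected(self):
        X = one_hot_matrix(np.zeros((5, 1), dtype=int))
        with pytest.raises(TrainingError):
            train_target_model(X, one_hot_matrix(np.zeros(5, dtype=int)))


class TestIntegerScaling:
    def _model(self, W, b):
        W = np.asarray(W, dtype=float)
        return TargetModel(target_id="t", selected_tags=["a"], W=W,
                           b=np.asarray(b, dtype=float))

    def test_scale_example(self):
        tm = self._model([[0.5, 0.25, 0.0]] * 3, [0, 0, 0])
        scale_to_int(tm, scale=8, weight_bits=8)
        assert tm.W_int[0].tolist() == [128, 64, 0]

    def test_scale_zero_rounds(self):
        tm = self._model([[0.6, 1.4, 0.0]] * 3, [0.5, 0, 0])
        scale_to_int(tm, scale=0, weight_bits=8)
        assert tm.W_int[0].tolist() == [1, 1, 0]

    def test_overflow_raises(self):
        tm = self._model([[1.5, 0, 0]] * 3, [0, 0, 0])
        with pytest.raises(ScaleOverflowError):
            scale_to_int(tm, scale=8, weight_bits=8)

    def test_rescale_to_fit_preserves_argmax_and_fits(self):
        rng = np.random.default_rng(5)
        W = rng.uniform(0, 3.0, (3, 6))
        b = rng.uniform(0, 3.0, 3)
        tm = self._model(W, b)
        X = one_hot_matrix(rng.integers(0, 3, (40, 2)))
        before = tm.predict(X, integer=False)
        rescale_to_fit(tm, scale=8, weight_bits=8)
        scale_to_int(tm, scale=8, weight_bits=8)
        assert (tm.predict(X, integer=False) == before).all()
        assert tm.W_int.max() <= 255 and tm.b_int.max() <= 255

    def test_argmax_agreement_under_rounding_bound(self):
        """When every sample's float top-2 score gap exceeds twice the
        worst-case rounding error (3k * 2^-scale terms of half-ulp each),
        integer and float argmax must coincide — brute force on random models."""
        rng = np.random.default_rng(6)
        k, scale = 4, 8
        bound = 2 * 3 * k * 2.0 ** (-scale)
        for trial in range(50):
            W = rng.uniform(0, 0.9, (3, 3 * k))
            b = rng.uniform(0, 0.9, 3)
            tm = self._model(W, b)
            scale_to_int(tm, scale=scale, weight_bits=8)
            X = one_hot_matrix(rng.integers(0, 3, (30, k)))
            sf = tm.scores_float(X)
            gaps = np.diff(np.sort(sf, axis=1)[:, -2:], axis=1)[:, 0]
            wide = gaps > bound
            if wide.any():
                assert (tm.predict(X[wide], integer=True)
                        == tm.predict(X[wide], integer=False)).all()


class TestClassProbabilities:
    def test_uniform_and_hand_case(self):
        assert class_probabilities(np.array([1.0, 1, 1])).tolist() == [1 / 3] * 3
        assert class_probabilities(np.array([3.0, 1, 0])).tolist() == [0.75, 0.25, 0.0]

    def test_zero_scores_give_uniform(self):
        assert class_probabilities(np.zeros(3)).tolist() == [1 / 3] * 3

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rows_sum_to_one_and_preserve_argmax(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.uniform(0, 10, (5, 3))
        p = class_probabilities(s)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert (np.argmax(p, axis=1) == np.argmax(s, axis=1)).all()

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            class_probabilities(np.array([-1.0, 1, 1]))


class TestCrossValidation:
    cfg = ModelConfig(k_tags=2, key_bits=256, train=TrainConfig(seed=0))

    def _learnable_panel(self, seed=0):
        # separable construction: each target is an exact copy of one tag,
        # so a linear one-hot model can be perfect
        rng = np.random.default_rng(seed)
        tags = rng.integers(0, 3, (150, 2), dtype=np.int8)
        G = np.column_stack([tags[:, 0], tags[:, 1], tags[:, 0], tags[:, 1]])
        meta = pd.DataFrame({
            "id": ["tagA", "tagB", "tgtA", "tgtB"],
            "chrom": ["1"] * 4,
            "pos": [100, 200, 300, 400],
            "role": ["tag", "tag", "target", "target"],
        })
        return GenotypeMatrix(G, meta)

    def test_folds_partition_all_individuals(self):
        panel = self._learnable_panel()
        out = cross_validate(panel, self.cfg, seed=1)
        flat = sorted(i for fold in out["folds"] for i in fold)
        assert flat == list(range(panel.n_individuals))

    def test_learnable_panel_scores_high(self):
        out = cross_validate(self._learnable_panel(), self.cfg, seed=1)
        assert out["mean_accuracy"] >= 0.99

    def test_shuffled_labels_fall_to_majority_baseline(self):
        panel = self._learnable_panel(seed=4)
        rng = np.random.default_rng(8)
        G = panel.genotypes.copy()
        majority = []
        for t in panel.target_ids:
            j = panel._index_of(t)
            G[:, j] = rng.permutation(G[:, j])
            counts = np.bincount(G[:, j], minlength=3)
            majority.append(counts.max() / counts.sum())
        shuffled = GenotypeMatrix(G, panel.snp_meta.copy())
        out = cross_validate(shuffled, self.cfg, seed=1)
        assert out["mean_accuracy"] == pytest.approx(np.mean(majority), abs=0.1)

    def test_too_few_individuals(self):
        panel = self._learnable_panel().subset_individuals(range(6))
        with pytest.raises(GenotypeError):
            cross_validate(panel, self.cfg)
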