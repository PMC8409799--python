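"""Per-target linear imputation models.

Each target SNP gets its own tiny linear classifier ("mini-model"): the top
``k`` tag SNPs ranked by mutual information with the target are one-hot
encoded (3 bits per tag) and mapped to three class scores by a non-negative
weight matrix ``W`` (3 x 3k) and bias ``b`` (3).  Training minimizes softmax
cross-entropy with Adam, projecting every parameter back to ``>= 0`` after
each update, so the encrypted pipeline never needs a negative-number
encoding.  After training, weights are scaled by ``2^scale`` and rounded to
integers that must fit ``weight_bits`` bits; the class with the largest
(raw, unnormalized) score is the predicted genotype, so per-class
normalization is only ever needed for ROC evaluation.

One-hot convention: genotype ``g`` sets position ``2 - g``, i.e. genotypes
[0, 1, 2] map to [0,0,1], [0,1,0] and [1,0,0].  The class order of score
vectors is therefore [2, 1, 0]: score position ``j`` votes for genotype
``2 - j``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, GenotypeError

__all__ = [
    "CLASS_ORDER",
    "TrainConfig",
    "ModelConfig",
    "TargetModel",
    "ImputationModel",
    "TrainingError",
    "ScaleOverflowError",
    "one_hot",
    "one_hot_matrix",
    "genotype_from_position",
    "mutual_information",
    "mi_table",
    "select_top_k",
    "train_target_model",
    "scale_to_int",
    "rescale_to_fit",
    "class_probabilities",
    "train_imputation_model",
    "cross_validate",
    "save_model",
    "load_model",
]

#: score position j corresponds to genotype CLASS_ORDER[j]
CLASS_ORDER: tuple[int, int, int] = (2, 1, 0)


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss) or received invalid data."""


class ScaleOverflowError(ValueError):
    """An integer-scaled parameter exceeds the weight bit budget."""


# ---------------------------------------------------------------------------
# encoding


def one_hot(g: int) -> np.ndarray:
    """One-hot encode a genotype: 0 -> [0,0,1], 1 -> [0,1,0], 2 -> [1,0,0]."""
    if g not in (0, 1, 2):
        raise GenotypeError(f"genotype must be 0, 1 or 2; got {g!r}")
    v = np.zeros(3, dtype=np.int8)
    v[2 - g] = 1
    return v


def genotype_from_position(pos: int) -> int:
    """Inverse of the one-hot convention: score/bit position -> genotype."""
    if pos not in (0, 1, 2):
        raise ValueError("position must be 0, 1 or 2")
    return CLASS_ORDER[pos]


def one_hot_matrix(columns: np.ndarray) -> np.ndarray:
    """One-hot encode genotype columns: (n, k) {0,1,2} -> (n, 3k) {0,1}.

    Tag blocks are laid out consecutively; within a block position ``j``
    indicates genotype ``2 - j``.
    """
    cols = np.atleast_2d(np.asarray(columns))
    if cols.ndim == 2 and cols.shape[0] == 1 and np.asarray(columns).ndim == 1:
        cols = cols.T
    n, k = cols.shape
    if not np.isin(cols, (0, 1, 2)).all():
        raise GenotypeError("genotypes must be coded 0/1/2")
    out = np.zeros((n, 3 * k), dtype=np.int8)
    rows = np.repeat(np.arange(n), k)
    positions = (np.arange(k) * 3 + (2 - cols)).ravel()
    out[rows, positions] = 1
    return out


# ---------------------------------------------------------------------------
# mutual information feature selection


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two genotype columns.

    ``I(X;Y) = sum_xy p(x,y) log[p(x,y) / (p(x) p(y))]`` with empirical
    frequencies; cells with ``p(x,y) = 0`` contribute zero.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise GenotypeError("columns must be equal-length 1-D arrays")
    n = len(x)
    if n < 2:
        raise GenotypeError("need at least 2 observations")
    joint = np.bincount(3 * x.astype(np.int64) + y.astype(np.int64),
                        minlength=9).reshape(3, 3) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    ratio = joint[nz] / (np.outer(px, py)[nz])
    return float(np.sum(joint[nz] * np.log(ratio)))


def mi_table(panel: GenotypeMatrix, train_rows: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Tag x target table of mutual-information scores (nats)."""
    G = panel.genotypes if train_rows is None else panel.genotypes[train_rows]
    tags, targets = panel.tag_ids, panel.target_ids
    tag_idx = [panel._index_of(t) for t in tags]
    tgt_idx = [panel._index_of(t) for t in targets]
    table = np.empty((len(tags), len(targets)))
    for a, ti in enumerate(tag_idx):
        xt = G[:, ti]
        for b, tj in enumerate(tgt_idx):
            table[a, b] = mutual_information(xt, G[:, tj])
    return pd.DataFrame(table, index=tags, columns=targets)


def select_top_k(scores: pd.DataFrame, target_id: str, k: int,
                 positions: dict[str, int]) -> list[str]:
    """The ``k`` tag SNPs with the highest MI for ``target_id``.

    Ties are broken by ascending genomic position, making the selection
    stable and deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(scores.index):
        raise ValueError(f"k={k} exceeds the {len(scores.index)} available tags")
    col = scores[target_id]
    order = sorted(scores.index, key=lambda t: (-col[t], positions[t]))
    return order[:k]


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer contract: Adam on softmax cross-entropy with per-update
    projection of all parameters to >= 0.

    The learning rate starts at 8e-4 with no decay, is halved after
    ``lr_patience`` consecutive non-improving epochs, floors at 1e-5, and
    training stops early after ``early_stop_patience`` further non-improving
    epochs at the floor.
    """

    epochs: int = 200
    lr: float = 8e-4
    lr_floor: float = 1e-5
    lr_patience: int = 3
    early_stop_patience: int = 10
    batch_size: Optional[int] = 32
    seed: int = 0
    init_scale: float = 0.01


@dataclass(frozen=True)
class ModelConfig:
    """End-to-end model hyperparameters."""

    k_tags: int = 10
    scale: int = 8
    weight_bits: int = 8
    key_bits: int = 3072
    train: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class TargetModel:
    """One target SNP's linear model and its integer-scaled counterpart."""

    target_id: str
    selected_tags: list[str]
    W: np.ndarray  # (3, 3k) float, >= 0
    b: np.ndarray  # (3,) float, >= 0
    scale: int = 8
    W_int: Optional[np.ndarray] = None  # (3, 3k) int64
    b_int: Optional[np.ndarray] = None  # (3,) int64
    class_order: tuple[int, int, int] = CLASS_ORDER
    int_float_agreement: Optional[float] = None

    def scores_float(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W.T + self.b

    def scores_int(self, X: np.ndarray) -> np.ndarray:
        if self.W_int is None:
            raise ValueError("model has not been integer-scaled")
        return X.astype(np.int64) @ self.W_int.T + self.b_int

    def predict(self, X: np.ndarray, integer: bool = True) -> np.ndarray:
        """Predicted genotypes; argmax ties resolve to the lowest position."""
        s = self.scores_int(X) if integer else self.scores_float(X)
        return np.asarray(self.class_order)[np.argmax(s, axis=1)]

    def max_slot_value(self) -> int:
        """Worst-case accumulated slot value under valid one-hot inputs.

        Per tag block exactly one input bit is set, so the worst case per
        class is the sum over blocks of the block's largest weight, plus the
        bias.
        """
        W = self.W_int.reshape(3, -1, 3)
        return int((W.max(axis=2).sum(axis=1) + self.b_int).max())


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=1, keepdims=True)


def _xent(P: np.ndarray, Y: np.ndarray) -> float:
    return float(-np.mean(np.sum(Y * np.log(P + 1e-12), axis=1)))


def train_target_model(
    X: np.ndarray,
    Y: np.ndarray,
    config: TrainConfig = TrainConfig(),
    target_id: str = "",
    selected_tags: Optional[list[str]] = None,
) -> TargetModel:
    """Fit non-negative ``W`` (3 x 3k) and ``b`` (3) by projected Adam.

    ``X`` is the one-hot tag matrix (n x 3k), ``Y`` the one-hot target matrix
    (n x 3).  A degenerate single-class target yields a bias-only model that
    always predicts that class.  Raises :class:`TrainingError` on a
    non-finite loss.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n, d = X.shape
    if n < 10:
        raise TrainingError(f"need at least 10 training rows, got {n}")
    if Y.shape != (n, 3) or not np.all(Y.sum(axis=1) == 1):
        raise TrainingError("Y must be a valid n x 3 one-hot matrix")

    present = Y.sum(axis=0) > 0
    if present.sum() == 1:
        # single-class target: bias-only majority model
        b = np.zeros(3)
        b[np.argmax(Y.sum(axis=0))] = 1.0
        return TargetModel(target_id=target_id,
                           selected_tags=selected_tags or [],
                           W=np.zeros((3, d)), b=b)

    rng = np.random.default_rng(config.seed)
    W = rng.uniform(0, config.init_scale, size=(3, d))
    b = rng.uniform(0, config.init_scale, size=3)
    mW, vW = np.zeros_like(W), np.zeros_like(W)
    mb, vb = np.zeros(3), np.zeros(3)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.lr
    best = np.inf
    stale = 0
    floor_stale = 0
    t = 0
    bs = config.batch_size or n
    for _epoch in range(config.epochs):
        order = rng.permutation(n) if config.batch_size else np.arange(n)
        for s in range(0, n, bs):
            rows = order[s:s + bs]
            P = _softmax(X[rows] @ W.T + b)
            G = (P - Y[rows]) / len(rows)
            gW = G.T @ X[rows]
            gb = G.sum(axis=0)
            t += 1
            mW = beta1 * mW + (1 - beta1) * gW
            vW = beta2 * vW + (1 - beta2) * gW ** 2
            mb = beta1 * mb + (1 - beta1) * gb
            vb = beta2 * vb + (1 - beta2) * gb ** 2
            W -= lr * (mW / (1 - beta1 ** t)) / (np.sqrt(vW / (1 - beta2 ** t)) + eps)
            b -= lr * (mb / (1 - beta1 ** t)) / (np.sqrt(vb / (1 - beta2 ** t)) + eps)
            np.clip(W, 0.0, None, out=W)  # projection: the non-negativity constraint
            np.clip(b, 0.0, None, out=b)
        loss = _xent(_softmax(X @ W.T + b), Y)
        if not np.isfinite(loss):
            raise TrainingError(
                f"non-finite loss at epoch {_epoch} (target {target_id!r}, lr={lr})"
            )
        if loss < best - 1e-7:
            best = loss
            stale = 0
            floor_stale = 0
        else:
            stale += 1
            if lr > config.lr_floor:
                if stale >= config.lr_patience:
                    lr = max(lr / 2, config.lr_floor)
                    stale = 0
            else:
                floor_stale += 1
                if floor_stale >= config.early_stop_patience:
                    break
    return TargetModel(target_id=target_id, selected_tags=selected_tags or [],
                       W=W, b=b)


# ---------------------------------------------------------------------------
# integer scaling


def scale_to_int(model: TargetModel, scale: int = 8, weight_bits: int = 8,
                 X_check: Optional[np.ndarray] = None) -> TargetModel:
    """Attach ``W_int = round(W * 2^scale)`` and ``b_int`` to the model.

    Raises :class:`ScaleOverflowError` if any scaled value needs more than
    ``weight_bits`` bits; in that case rescale the float weights first (see
    :func:`rescale_to_fit`) or reduce ``scale``.  When ``X_check`` is given,
    the fraction of rows where the integer and float argmax agree is recorded
    on the model.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if (model.W < 0).any() or (model.b < 0).any():
        raise ValueError("float weights must be non-negative before scaling")
    factor = 1 << scale
    W_int = np.rint(model.W * factor).astype(np.int64)
    b_int = np.rint(model.b * factor).astype(np.int64)
    top = max(int(W_int.max(initial=0)), int(b_int.max(initial=0)))
    if top >= (1 << weight_bits):
        raise ScaleOverflowError(
            f"scaled weight {top} needs more than {weight_bits} bits; "
            "renormalize the float weights or reduce scale"
        )
    model.scale = scale
    model.W_int = W_int
    model.b_int = b_int
    if X_check is not None and len(X_check):
        fa = model.predict(X_check, integer=False)
        ia = model.predict(X_check, integer=True)
        model.int_float_agreement = float(np.mean(fa == ia))
    return model


def rescale_to_fit(model: TargetModel, scale: int = 8, weight_bits: int = 8) -> TargetModel:
    """Divide ``(W, b)`` by a common positive factor so the scaled integers fit.

    Multiplying all of a target's scores by one positive constant changes
    neither the argmax prediction nor the per-sample normalized
    probabilities, so this is a lossless remedy for scale overflow.
    """
    top = max(float(model.W.max(initial=0.0)), float(model.b.max(initial=0.0)))
    limit = ((1 << weight_bits) - 1) / (1 << scale)
    if top > limit:
        f = limit / top
        model.W = model.W * f
        model.b = model.b * f
    return model


def class_probabilities(scores: np.ndarray) -> np.ndarray:
    """Normalize non-negative class scores to probabilities (rows sum to 1).

    All-zero rows map to the uniform distribution.  Normalization preserves
    the argmax, which is why the encrypted server never computes it:
    probabilities are only needed for ROC evaluation.
    """
    s = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    if (s < 0).any():
        raise ValueError("scores must be non-negative (constraint violated upstream)")
    total = s.sum(axis=1, keepdims=True)
    out = np.full_like(s, 1.0 / s.shape[1])
    nz = total[:, 0] > 0
    out[nz] = s[nz] / total[nz]
    return out if np.asarray(scores).ndim == 2 else out[0]


# ---------------------------------------------------------------------------
# whole-panel orchestration


@dataclass
class ImputationModel:
    """All per-target models plus training provenance."""

    targets: list[TargetModel]
    config: ModelConfig

    @property
    def target_ids(self) -> list[str]:
        return [t.target_id for t in self.targets]

    @property
    def all_selected_tags(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.targets:
            for tag in t.selected_tags:
                seen.setdefault(tag, None)
        return list(seen)

    def predict(self, tag_panel: GenotypeMatrix, integer: bool = True):
        """Plaintext inference: (n x n_targets genotypes, n x n_targets x 3 scores)."""
        n = tag_panel.n_individuals
        geno = np.zeros((n, len(self.targets)), dtype=np.int8)
        scores = np.zeros((n, len(self.targets), 3))
        for j, tm in enumerate(self.targets):
            X = one_hot_matrix(np.column_stack([tag_panel.column(t)
                                                for t in tm.selected_tags]))
            s = tm.scores_int(X) if integer else tm.scores_float(X)
            scores[:, j, :] = s
            geno[:, j] = np.asarray(tm.class_order)[np.argmax(s, axis=1)]
        return geno, scores


def train_imputation_model(
    panel: GenotypeMatrix,
    config: ModelConfig = ModelConfig(),
    train_rows: Optional[np.ndarray] = None,
    label_override: Optional[dict[str, np.ndarray]] = None,
) -> ImputationModel:
    """MI selection + constrained training + integer scaling for every target.

    ``label_override`` substitutes training labels per target id (used by
    chance-level controls); feature columns are never altered.
    """
    rows = np.arange(panel.n_individuals) if train_rows is None else np.asarray(train_rows)
    scores = mi_table(panel, rows)
    positions = {t: panel.position_of(t) for t in panel.tag_ids}
    models = []
    for target in panel.target_ids:
        top = select_top_k(scores, target, config.k_tags, positions)
        X = one_hot_matrix(np.column_stack([panel.column(t)[rows] for t in top]))
        y = panel.column(target)[rows]
        if label_override and target in label_override:
            y = label_override[target]
        Y = one_hot_matrix(y)
        tm = train_target_model(X, Y, config.train, target_id=target,
                                selected_tags=top)
        rescale_to_fit(tm, config.scale, config.weight_bits)
        scale_to_int(tm, config.scale, config.weight_bits, X_check=X)
        models.append(tm)
    return ImputationModel(targets=models, config=config)


def cross_validate(panel: GenotypeMatrix, config: ModelConfig = ModelConfig(),
                   n_folds: int = 5, seed: int = 0) -> dict:
    """k-fold cross-validation (default 5) of plaintext imputation accuracy.

    Individuals are shuffled deterministically by ``seed`` and partitioned
    into ``n_folds`` validation folds; for each fold the model is trained on
    the remainder and scored on the fold.
    """
    n = panel.n_individuals
    if n < n_folds * 2:
        raise GenotypeError(f"too few individuals ({n}) for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    accs = []
    for fold in folds:
        train_rows = np.setdiff1d(order, fold)
        model = train_imputation_model(panel, config, train_rows=train_rows)
        val = panel.subset_individuals(fold)
        pred, _ = model.predict(val.tags_only())
        truth = np.column_stack([val.column(t) for t in model.target_ids])
        accs.append(float(np.mean(pred == truth)))
    return {"fold_accuracy": accs, "mean_accuracy": float(np.mean(accs)),
            "folds": [fold.tolist() for fold in folds]}


# ---------------------------------------------------------------------------
# serialization


def save_model(model: ImputationModel, path: str | Path) -> None:
    doc = {
        "key_bits": model.config.key_bits,
        "weight_bits": model.config.weight_bits,
        "scale": model.config.scale,
        "k_tags": model.config.k_tags,
        "class_order": list(CLASS_ORDER),
        "train": asdict(model.config.train),
        "targets": [
            {
                "target_id": tm.target_id,
                "selected_tags": tm.selected_tags,
                "W_int": tm.W_int.tolist(),
                "b_int": tm.b_int.tolist(),
                "W": tm.W.tolist(),
                "b": tm.b.tolist(),
                "int_float_agreement": tm.int_float_agreement,
            }
            for tm in model.targets
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def load_model(path: str | Path) -> ImputationModel:
    doc = json.loads(Path(path).read_text())
    train = TrainConfig(**doc["train"])
    config = ModelConfig(k_tags=doc["k_tags"], scale=doc["scale"],
                         weight_bits=doc["weight_bits"], key_bits=doc["key_bits"],
                         train=train)
    targets = []
    for td in doc["targets"]:
        tm = TargetModel(
            target_id=td["target_id"],
            selected_tags=list(td["selected_tags"]),
            W=np.asarray(td["W"], dtype=np.float64),
            b=np.asarray(td["b"], dtype=np.float64),
            scale=doc["scale"],
            W_int=np.asarray(td["W_int"], dtype=np.int64),
            b_int=np.asarray(td["b_int"], dtype=np.int64),
            int_float_agreement=td.get("int_float_agreement"),
        )
        targets.append(tm)
    return ImputationModel(targets=targets, config=config)
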