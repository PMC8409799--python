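"""Client/server protocol for encrypted imputation.

The client one-hot encodes its tag-SNP genotypes, packs the bits of up to
``slot_count`` consecutive individuals into one plaintext per (tag, one-hot
position), and encrypts.  Only tag SNPs selected by at least one target
model are encrypted; positions shared by several target models are encrypted
once and reused.  The server — holding only the public key and the plaintext
integer weights — accumulates, per target and class,
``hom_scalar_mult(ciphertext, W_int)`` over the non-zero weights and adds the
packed bias, producing one ciphertext per (target, class, batch) whose slots
decrypt to ``W_int . x + b_int`` for each individual.  The client decrypts
each result ciphertext once, unpacks the slots, and predicts the genotype
with the largest raw score; because all weights are non-negative integers,
the encrypted pipeline is bit-exact equal to plaintext integer inference.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import paillier
from .paillier import Ciphertext, KeyPair, PublicKey, hom_add, hom_add_plaintext, hom_scalar_mult
from .packing import SlotLayout, PackingError, pack, unpack
from .genotypes import GenotypeMatrix, GenotypeError
from .model import ImputationModel, one_hot_matrix

__all__ = [
    "EncryptedQuery",
    "EncryptedResult",
    "PredictionTable",
    "ProtocolError",
    "model_layout",
    "client_encrypt",
    "server_impute",
    "client_decrypt_predict",
]


class ProtocolError(RuntimeError):
    """Key/layout mismatch or blindness-contract violation."""


def model_layout(model: ImputationModel, key_bits: Optional[int] = None) -> SlotLayout:
    """Slot layout sized for the model's 3k one-hot inputs plus the bias."""
    kb = key_bits if key_bits is not None else model.config.key_bits
    return SlotLayout.for_model(kb, model.config.weight_bits,
                                3 * model.config.k_tags, include_bias=True)


@dataclass
class EncryptedQuery:
    """Encrypted one-hot bit columns for up to ``n_individuals`` individuals.

    ``bits[(tag_id, pos)]`` is one ciphertext per batch; slot ``i`` of batch
    ``b`` holds the bit of individual ``sum(batch_sizes[:b]) + i``.
    """

    bits: dict[tuple[str, int], list[Ciphertext]]
    layout: SlotLayout
    n_individuals: int
    batch_sizes: list[int]
    key_fingerprint: str
    individual_ids: Optional[list[str]] = None


@dataclass
class EncryptedResult:
    """Per (target, class): one packed score ciphertext per batch."""

    scores: dict[str, list[list[Ciphertext]]]  # target -> [class 0..2] -> [batch]
    layout: SlotLayout
    n_individuals: int
    batch_sizes: list[int]
    key_fingerprint: str
    target_ids: list[str] = field(default_factory=list)


@dataclass
class PredictionTable:
    """Per-individual, per-target predicted genotypes and raw integer scores."""

    genotypes: np.ndarray  # (n, n_targets) int8
    scores: np.ndarray  # (n, n_targets, 3) int64
    target_ids: list[str]
    individual_ids: list[str]


def _batch_slices(n: int, batch_size: int) -> list[slice]:
    return [slice(s, min(s + batch_size, n)) for s in range(0, n, batch_size)]


def client_encrypt(
    tag_panel: GenotypeMatrix,
    model: ImputationModel,
    kp: KeyPair,
    batch_size: Optional[int] = None,
) -> EncryptedQuery:
    """Encrypt the one-hot bits of every tag SNP any target model selects.

    ``batch_size`` defaults to the layout's slot count (236 for the 13-bit /
    3072-bit default); a query of more individuals spans multiple ciphertexts
    per position, the last one padded with zero slots.
    """
    layout = model_layout(model, kp.public.key_bits)
    if batch_size is None:
        batch_size = layout.slot_count
    if batch_size < 1 or batch_size > layout.slot_count:
        raise ProtocolError(
            f"batch size {batch_size} outside [1, {layout.slot_count}] for this layout"
        )
    needed = model.all_selected_tags
    have = set(tag_panel.snp_ids)
    missing = [t for t in needed if t not in have]
    if missing:
        raise GenotypeError(f"query lacks required tag SNPs: {missing}")
    n = tag_panel.n_individuals
    slices = _batch_slices(n, batch_size)
    bits: dict[tuple[str, int], list[Ciphertext]] = {}
    for tag in needed:
        onehot = one_hot_matrix(tag_panel.column(tag))  # (n, 3)
        for pos in range(3):
            col = onehot[:, pos]
            cts = []
            for sl in slices:
                packed = pack(col[sl].tolist(), layout)
                ct = paillier.encrypt(packed, kp.public,
                                      zero_cache=kp.zero_cache,
                                      power_table=kp.power_table)
                cts.append(ct.with_layout(layout))
            bits[(tag, pos)] = cts
    return EncryptedQuery(
        bits=bits,
        layout=layout,
        n_individuals=n,
        batch_sizes=[sl.stop - sl.start for sl in slices],
        key_fingerprint=kp.public.fingerprint,
        individual_ids=list(tag_panel.individual_ids),
    )


def _check_server_key(pk) -> PublicKey:
    if isinstance(pk, KeyPair):
        raise ProtocolError(
            "server_impute accepts a PublicKey only; a KeyPair may carry "
            "private material (server blindness contract)"
        )
    if not isinstance(pk, PublicKey):
        raise ProtocolError(f"expected a PublicKey, got {type(pk).__name__}")
    return pk


def server_impute(
    query: EncryptedQuery,
    model: ImputationModel,
    pk: PublicKey,
    threads: int = 1,
    skip_zero_weights: bool = True,
    power_table=None,
) -> EncryptedResult:
    """Encrypted linear scores for every target, class, and batch.

    Homomorphic work is skipped for zero weights (they contribute nothing to
    the sum).  Targets are processed in a thread pool when ``threads > 1``;
    the per-(target, class, batch) accumulation order is fixed, so results
    are independent of the thread count.
    """
    pk = _check_server_key(pk)
    if query.key_fingerprint != pk.fingerprint:
        raise ProtocolError("query was encrypted under a different public key")
    layout = query.layout
    limit = 1 << layout.slot_bits
    for tm in model.targets:
        worst = tm.max_slot_value()
        if worst >= limit:
            raise ProtocolError(
                f"target {tm.target_id}: worst-case slot value {worst} exceeds the "
                f"{layout.slot_bits}-bit slot budget; refuse to corrupt neighbor slots"
            )

    def impute_target(tm):
        per_class = []
        for cls in range(3):
            cts = []
            for bi, bsz in enumerate(query.batch_sizes):
                acc: Optional[Ciphertext] = None
                for ti, tag in enumerate(tm.selected_tags):
                    for pos in range(3):
                        w = int(tm.W_int[cls, 3 * ti + pos])
                        if w == 0 and skip_zero_weights:
                            continue
                        term = hom_scalar_mult(query.bits[(tag, pos)][bi], w, pk)
                        acc = term if acc is None else hom_add(acc, term, pk)
                bias = int(tm.b_int[cls])
                packed_bias = pack([bias] * bsz, layout)
                if acc is None:
                    acc = Ciphertext(1, layout)  # deterministic zero
                if packed_bias:
                    acc = hom_add_plaintext(acc, packed_bias, pk, power_table)
                cts.append(acc.with_layout(layout))
            per_class.append(cts)
        return tm.target_id, per_class

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(impute_target, model.targets))
    else:
        results = [impute_target(tm) for tm in model.targets]
    return EncryptedResult(
        scores=dict(results),
        layout=layout,
        n_individuals=query.n_individuals,
        batch_sizes=list(query.batch_sizes),
        key_fingerprint=query.key_fingerprint,
        target_ids=[tm.target_id for tm in model.targets],
    )


def client_decrypt_predict(
    result: EncryptedResult,
    kp: KeyPair,
    model: ImputationModel,
    individual_ids: Optional[list[str]] = None,
) -> PredictionTable:
    """Decrypt each result ciphertext once, unpack, and predict genotypes.

    Prediction is the class with the maximal raw integer score (ties resolve
    to the lowest one-hot position, i.e. the highest genotype).  A slot value
    at or above ``2^slot_bits`` indicates an integrity failure and is
    rejected with the offending target named.
    """
    if kp.private is None:
        raise paillier.MissingPrivateKeyError("prediction requires the private key")
    if result.key_fingerprint != kp.public.fingerprint:
        raise ProtocolError("result was computed under a different public key")
    layout = result.layout
    n = result.n_individuals
    n_targets = len(result.target_ids)
    scores = np.zeros((n, n_targets, 3), dtype=np.int64)
    limit = 1 << layout.slot_bits
    for j, target in enumerate(result.target_ids):
        for cls in range(3):
            offset = 0
            for bi, bsz in enumerate(result.batch_sizes):
                plain = paillier.decrypt(result.scores[target][cls][bi], kp)
                vals = unpack(plain, layout, bsz)
                if any(v >= limit for v in vals):
                    raise ProtocolError(
                        f"slot overflow detected in target {target} (corrupt result)"
                    )
                scores[offset:offset + bsz, j, cls] = vals
                offset += bsz
    class_order = np.asarray(model.targets[0].class_order if model.targets else (2, 1, 0))
    genotypes = class_order[np.argmax(scores, axis=2)].astype(np.int8)
    ids = individual_ids or [f"ind{i:05d}" for i in range(n)]
    return PredictionTable(genotypes=genotypes, scores=scores,
                           target_ids=list(result.target_ids),
                           individual_ids=ids)
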