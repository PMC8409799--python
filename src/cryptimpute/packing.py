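"""Slot packing: many individuals' small values in one Paillier plaintext.

The Paillier plaintext space (``key_bits`` bits) vastly exceeds the width of
one imputation score, so consecutive individuals are packed into disjoint
bit ranges ("slots") of a single plaintext before encryption.  Because
homomorphic addition acts independently on non-overlapping bit ranges as
long as no slot overflows, one ciphertext then carries one score for each of
``floor(key_bits / slot_bits)`` individuals through the whole encrypted
linear evaluation.

The slot width is sized for the worst case of the linear model: with 1-bit
one-hot inputs and ``weight_bits``-bit weights, a sum of ``n`` products needs
``weight_bits + ceil(log2 n)`` bits.  For the default model (10 tag SNPs,
30 one-hot inputs, 8-bit weights) that is ``8 + ceil(log2 30) = 13`` bits,
hence ``floor(3072 / 13) = 236`` individuals per ciphertext at a 3072-bit
key.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["SlotLayout", "slot_width", "capacity", "pack", "unpack", "PackingError"]


class PackingError(ValueError):
    """A value does not fit its slot, or a packed integer exceeds the layout."""


def slot_width(weight_bits: int, n_onehot_inputs: int) -> int:
    """Bits needed for a sum of ``n_onehot_inputs`` (1-bit input x weight) products.

    Returns ``weight_bits + ceil(log2(n_onehot_inputs))``.
    """
    if weight_bits < 1:
        raise ValueError("weight_bits must be >= 1")
    if n_onehot_inputs < 1:
        raise ValueError("n_onehot_inputs must be >= 1")
    return weight_bits + (n_onehot_inputs - 1).bit_length()


def capacity(key_bits: int, slot_bits: int) -> int:
    """Individuals per ciphertext: ``floor(key_bits / slot_bits)``; 0 = impossible."""
    if key_bits < 1 or slot_bits < 1:
        raise ValueError("key_bits and slot_bits must be >= 1")
    return key_bits // slot_bits


@dataclass(frozen=True)
class SlotLayout:
    """Slot geometry: width per individual, slot count, and ordering convention.

    ``order`` is fixed to least-significant-slot-first: slot ``i`` occupies
    bits ``[i*slot_bits, (i+1)*slot_bits)``.
    """

    slot_bits: int
    slot_count: int
    key_bits: int
    order: str = "lsb-first"

    def __post_init__(self) -> None:
        if self.slot_bits < 1:
            raise ValueError("slot_bits must be >= 1")
        if self.slot_count < 1:
            raise PackingError(
                f"key of {self.key_bits} bits cannot host a {self.slot_bits}-bit slot"
            )
        if self.slot_count != self.key_bits // self.slot_bits:
            raise ValueError("slot_count must equal floor(key_bits / slot_bits)")
        if self.order != "lsb-first":
            raise ValueError("only lsb-first slot order is supported")

    @classmethod
    def build(cls, key_bits: int, slot_bits: int) -> "SlotLayout":
        return cls(slot_bits=slot_bits, slot_count=capacity(key_bits, slot_bits),
                   key_bits=key_bits)

    @classmethod
    def for_model(
        cls,
        key_bits: int,
        weight_bits: int,
        n_onehot_inputs: int,
        include_bias: bool = True,
    ) -> "SlotLayout":
        """Layout sized for a linear model's accumulated slot value.

        With ``include_bias`` (default) the bias counts as one extra addend,
        so the slot is sized for ``n_onehot_inputs + 1`` terms.  For the
        10-tag model both conventions give 13 bits (``ceil(log2 31) = 5``).
        """
        n = n_onehot_inputs + (1 if include_bias else 0)
        return cls.build(key_bits, slot_width(weight_bits, n))

    @property
    def slot_mask(self) -> int:
        return (1 << self.slot_bits) - 1

    def to_dict(self) -> dict:
        return {"slot_bits": self.slot_bits, "slot_count": self.slot_count,
                "key_bits": self.key_bits, "order": self.order}

    @classmethod
    def from_dict(cls, d: dict) -> "SlotLayout":
        return cls(slot_bits=int(d["slot_bits"]), slot_count=int(d["slot_count"]),
                   key_bits=int(d["key_bits"]), order=d.get("order", "lsb-first"))


def pack(values: Sequence[int], layout: SlotLayout) -> int:
    """Pack ``values`` into one integer: ``sum(values[i] << (i * slot_bits))``.

    Trailing slots are zero.  A value outside ``[0, 2^slot_bits)`` would
    corrupt a neighboring slot and raises :class:`PackingError`.
    """
    if len(values) > layout.slot_count:
        raise PackingError(
            f"{len(values)} values exceed {layout.slot_count} slots"
        )
    limit = 1 << layout.slot_bits
    packed = 0
    for i, v in enumerate(values):
        v = int(v)
        if not 0 <= v < limit:
            raise PackingError(
                f"value {v} at slot {i} does not fit {layout.slot_bits} bits"
            )
        packed |= v << (i * layout.slot_bits)
    return packed


def unpack(packed: int, layout: SlotLayout, n: int) -> list[int]:
    """First ``n`` slot values of ``packed`` via shift-right and mask."""
    if n > layout.slot_count:
        raise PackingError(f"cannot unpack {n} slots from a {layout.slot_count}-slot layout")
    if packed < 0 or packed >= 1 << (layout.slot_bits * layout.slot_count):
        raise PackingError("packed integer exceeds the layout (layout mismatch)")
    mask = layout.slot_mask
    return [(packed >> (i * layout.slot_bits)) & mask for i in range(n)]
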