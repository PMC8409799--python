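"""Slot packing: how 236 individuals share one 3072-bit ciphertext.

The per-individual score of a 10-tag linear model (30 one-hot inputs, 8-bit
weights, plus a bias) never exceeds 13 bits, so a 3072-bit plaintext packs
floor(3072/13) = 236 individuals.  Adding two packed integers adds every
slot independently as long as no slot overflows — which is why one
homomorphic addition advances all 236 individuals at once.
"""

from cryptimpute.packing import SlotLayout, capacity, pack, slot_width, unpack

w = slot_width(8, 30)
print(f"slot width for 8-bit weights, 30 one-hot inputs: {w} bits")
print(f"individuals per 3072-bit ciphertext: {capacity(3072, w)}")

layout = SlotLayout.build(16, 4)  # miniature layout: four 4-bit slots
a = [3, 1, 2]
b = [2, 5, 1]
pa_, pb = pack(a, layout), pack(b, layout)
print(f"pack({a}) = {pa_}  (= 3 + 1*16 + 2*256)")
print(f"unpack  -> {unpack(pa_, layout, 3)}")
print(f"unpack(pack({a}) + pack({b})) = {unpack(pa_ + pb, layout, 3)} "
      "(slotwise sums, one integer addition)")
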