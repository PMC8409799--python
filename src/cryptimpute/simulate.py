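"""Synthetic diploid genotype panels with haplotype-block LD structure.

Imputation works because SNPs within a haplotype block are in linkage
disequilibrium: individuals inherit whole block haplotypes from a small pool
of ancestors, so observing a few tag SNPs pins down the haplotype pair and
with it the unobserved target SNPs.  The generator reproduces exactly that
mechanism in its simplest form: per block, a small pool of founder binary
haplotypes is drawn, each individual samples two founders uniformly (with
replacement) and flips each inherited allele with a per-site mutation rate;
the genotype is the allele sum in {0, 1, 2}.  Blocks are unlinked (free
recombination between blocks), so cross-block mutual information is ~0 and
MI-based tag selection has a well-defined correct answer.

``mutation_rate`` is the learnability dial: 0 makes every same-block SNP a
deterministic function of the (unordered) founder pair; raising it decays
within-block LD toward independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .model import (
    CLASS_ORDER,
    ImputationModel,
    ModelConfig,
    TargetModel,
    TrainConfig,
)

__all__ = ["SimConfig", "simulate_panel", "make_worked_fixture"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic panel.

    Defaults give 2,000 individuals over 13 blocks of 10 SNPs each with a
    60/40 tag/target split (78 tags, 52 targets), 4 founder haplotypes per
    block, and a 1% per-site mutation rate — a high-LD panel on which the
    10-tag linear models are comfortably learnable.
    """

    n_individuals: int = 2000
    n_blocks: int = 13
    snps_per_block: int = 10
    founder_haplotypes_per_block: int = 4
    mutation_rate: float = 0.01
    tag_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_blocks", "snps_per_block",
                     "founder_haplotypes_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0.0 <= self.tag_fraction <= 1.0:
            raise ValueError("tag_fraction must be in [0, 1]")


def simulate_panel(cfg: SimConfig) -> GenotypeMatrix:
    """Generate a reproducible panel under the founder-resampling model.

    Within each block the first ``round(tag_fraction * snps_per_block)``
    SNPs are tags and the remainder targets, so the tag/target split is a
    deterministic partition of all SNPs.
    """
    if cfg.founder_haplotypes_per_block == 1 and cfg.mutation_rate == 0.0:
        warnings.warn("a single founder with zero mutation yields a monomorphic panel",
                      stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    n, spb = cfg.n_individuals, cfg.snps_per_block
    n_tags_per_block = round(cfg.tag_fraction * spb)
    G = np.zeros((n, cfg.n_blocks * spb), dtype=np.int8)
    ids, chroms, positions, roles = [], [], [], []
    for b in range(cfg.n_blocks):
        founders = rng.integers(0, 2, size=(cfg.founder_haplotypes_per_block, spb),
                                dtype=np.int8)
        draw1 = rng.integers(0, cfg.founder_haplotypes_per_block, size=n)
        draw2 = rng.integers(0, cfg.founder_haplotypes_per_block, size=n)
        hap1 = founders[draw1]
        hap2 = founders[draw2]
        if cfg.mutation_rate > 0:
            hap1 = hap1 ^ (rng.random((n, spb)) < cfg.mutation_rate)
            hap2 = hap2 ^ (rng.random((n, spb)) < cfg.mutation_rate)
        G[:, b * spb:(b + 1) * spb] = hap1.astype(np.int8) + hap2.astype(np.int8)
        for i in range(spb):
            ids.append(f"b{b:02d}s{i:02d}")
            chroms.append("1")
            positions.append(b * 10_000 + (i + 1) * 100)
            roles.append("tag" if i < n_tags_per_block else "target")
    meta = pd.DataFrame({"id": ids, "chrom": chroms, "pos": positions, "role": roles})
    return GenotypeMatrix(genotypes=G, snp_meta=meta)


# ---------------------------------------------------------------------------
# worked fixture: small enough to check every number by hand


#: expected plaintext-integer predictions for the worked fixture
#: (8 individuals x 2 targets), frozen from hand evaluation of the
#: fixture's lookup-table weights on the fixture genotypes.
_FIXTURE_EXPECTED = np.array(
    [
        [2, 0],
        [1, 1],
        [0, 2],
        [1, 1],
        [2, 0],
        [0, 2],
        [1, 1],
        [2, 0],
    ],
    dtype=np.int8,
)


def make_worked_fixture() -> tuple[GenotypeMatrix, ImputationModel, np.ndarray]:
    """A tiny deterministic panel, a hand-built integer model, and the
    expected predictions.

    Two unlinked blocks of two SNPs each; within a block the tag and target
    are perfect copies (two complementary founders, no mutation), so the
    correct model is a lookup table: the weight block of the copied tag is
    ``64 * I`` (one-hot position j votes for class j) and all other weights
    are zero.  Every prediction equals the tag genotype, hand-checkable row
    by row.
    """
    # genotypes chosen directly (valid founder-pair draws for founders
    # 01 / 10 per block with tag == target within a block)
    tag0 = np.array([2, 1, 0, 1, 2, 0, 1, 2], dtype=np.int8)
    tag1 = np.array([0, 1, 2, 1, 0, 2, 1, 0], dtype=np.int8)
    G = np.column_stack([tag0, tag0, tag1, tag1])
    meta = pd.DataFrame({
        "id": ["b00s00", "b00s01", "b01s00", "b01s01"],
        "chrom": ["1", "1", "1", "1"],
        "pos": [100, 200, 10100, 10200],
        "role": ["tag", "target", "tag", "target"],
    })
    panel = GenotypeMatrix(genotypes=G, snp_meta=meta)

    config = ModelConfig(k_tags=1, scale=8, weight_bits=8, key_bits=256,
                         train=TrainConfig(seed=0))
    targets = []
    for target_id, tag_id in (("b00s01", "b00s00"), ("b01s01", "b01s00")):
        W = np.eye(3) * 0.25  # 0.25 * 2^8 = 64
        b = np.zeros(3)
        tm = TargetModel(target_id=target_id, selected_tags=[tag_id],
                         W=W, b=b, scale=8,
                         W_int=(W * 256).astype(np.int64),
                         b_int=b.astype(np.int64),
                         class_order=CLASS_ORDER)
        targets.append(tm)
    model = ImputationModel(targets=targets, config=config)
    return panel, model, _FIXTURE_EXPECTED.copy()
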