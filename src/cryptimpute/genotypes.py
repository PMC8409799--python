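"""Genotype matrix container: individuals x SNPs with tag/target roles.

Genotypes are count-coded diploid states: 0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternative.  Each SNP carries an id, a
chromosome, a 1-based position, and a role: ``tag`` (observed predictor) or
``target`` (to be imputed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "GenotypeError"]

META_COLUMNS = ("id", "chrom", "pos", "role")


class GenotypeError(ValueError):
    """Invalid genotype data."""


@dataclass
class GenotypeMatrix:
    """``genotypes[i, j]`` is the {0,1,2} genotype of individual ``i`` at SNP ``j``."""

    genotypes: np.ndarray
    snp_meta: pd.DataFrame  # columns: id, chrom, pos, role
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise GenotypeError("genotypes must be a 2-D individuals x SNPs array")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise GenotypeError("genotypes must be coded 0/1/2 (missing values rejected)")
        meta = self.snp_meta
        for col in META_COLUMNS:
            if col not in meta.columns:
                raise GenotypeError(f"snp_meta lacks required column {col!r}")
        if len(meta) != self.genotypes.shape[1]:
            raise GenotypeError("snp_meta rows must match genotype columns")
        if meta["id"].duplicated().any():
            raise GenotypeError("SNP ids must be unique")
        if not meta["role"].isin(("tag", "target")).all():
            raise GenotypeError("SNP role must be 'tag' or 'target'")
        for _, grp in meta.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise GenotypeError("positions must be strictly increasing within a chromosome")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i:05d}" for i in range(self.genotypes.shape[0])]
        if len(self.individual_ids) != self.genotypes.shape[0]:
            raise GenotypeError("individual_ids must match genotype rows")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_meta["id"].tolist()

    @property
    def tag_ids(self) -> list[str]:
        return self.snp_meta.loc[self.snp_meta["role"] == "tag", "id"].tolist()

    @property
    def target_ids(self) -> list[str]:
        return self.snp_meta.loc[self.snp_meta["role"] == "target", "id"].tolist()

    def column(self, snp_id: str) -> np.ndarray:
        idx = self._index_of(snp_id)
        return self.genotypes[:, idx]

    def _index_of(self, snp_id: str) -> int:
        matches = np.flatnonzero((self.snp_meta["id"] == snp_id).to_numpy())
        if len(matches) == 0:
            raise GenotypeError(f"unknown SNP id {snp_id!r}")
        return int(matches[0])

    def position_of(self, snp_id: str) -> int:
        return int(self.snp_meta.iloc[self._index_of(snp_id)]["pos"])

    def restrict_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._index_of(s) for s in snp_ids]
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx].copy(),
            snp_meta=self.snp_meta.iloc[idx].reset_index(drop=True),
            individual_ids=list(self.individual_ids),
        )

    def tags_only(self) -> "GenotypeMatrix":
        return self.restrict_snps(self.tag_ids)

    def targets_only(self) -> "GenotypeMatrix":
        return self.restrict_snps(self.target_ids)

    def subset_individuals(self, rows) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            genotypes=self.genotypes[rows].copy(),
            snp_meta=self.snp_meta.copy(),
            individual_ids=[self.individual_ids[i] for i in rows],
        )

    def split(self, n_first: int) -> tuple["GenotypeMatrix", "GenotypeMatrix"]:
        """Deterministic head/tail split (e.g. train/test)."""
        idx = np.arange(self.n_individuals)
        return self.subset_individuals(idx[:n_first]), self.subset_individuals(idx[n_first:])
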