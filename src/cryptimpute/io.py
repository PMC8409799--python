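"""File formats: genotype panels (VCF / TSV), tag manifests, wire envelopes.

VCF dialect: VCFv4.2, biallelic records (REF=A, ALT=G placeholders for
synthetic panels), unphased diploid GT ("0/0", "0/1", "1/1" -> 0, 1, 2),
1-based positions, with the tag/target role carried in INFO as ``ROLE=``.
Missing genotypes ("./.") are rejected — the pipeline assumes complete
panels.  Reading goes through cyvcf2 (htslib); writing emits the fixed
dialect directly.

Wire envelopes (encrypted query / result) are JSON: protocol version, key
fingerprint, slot layout, and hexadecimal ciphertexts.  In strict-privacy
mode the individual-id manifest stays client-side and the envelope carries
only counts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import GenotypeMatrix, GenotypeError
from .inference import EncryptedQuery, EncryptedResult, PredictionTable
from .packing import SlotLayout
from .paillier import Ciphertext

__all__ = [
    "write_vcf", "read_vcf", "write_tsv", "read_tsv",
    "write_manifest", "read_manifest",
    "save_query", "load_query", "save_result", "load_result",
    "write_predictions_tsv", "write_predictions_vcf",
]

PROTOCOL_VERSION = 1


# ---------------------------------------------------------------------------
# panels


def write_vcf(panel: GenotypeMatrix, path: str | Path) -> None:
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=ROLE,Number=1,Type=String,Description="tag or target SNP">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in panel.snp_meta["chrom"].unique():
        lines.append(f"##contig=<ID={chrom}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += list(panel.individual_ids)
    lines.append("\t".join(header))
    for j in range(panel.n_snps):
        meta = panel.snp_meta.iloc[j]
        row = [str(meta["chrom"]), str(int(meta["pos"])), str(meta["id"]),
               "A", "G", ".", "PASS", f"ROLE={meta['role']}", "GT"]
        row += gt_strings[panel.genotypes[:, j]].tolist()
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, manifest: Optional[dict[str, str]] = None) -> GenotypeMatrix:
    """Parse a VCF into a panel; roles come from INFO/ROLE or a manifest."""
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    ids, chroms, positions, roles, columns = [], [], [], [], []
    for variant in vcf:
        sid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        role = variant.INFO.get("ROLE")
        if manifest is not None:
            role = manifest.get(sid, role)
        if role not in ("tag", "target"):
            raise GenotypeError(f"SNP {sid}: no tag/target role in INFO or manifest")
        col = np.empty(len(individuals), dtype=np.int8)
        for i, g in enumerate(variant.genotypes):
            a, b = int(g[0]), int(g[1])
            if a < 0 or b < 0:
                raise GenotypeError(f"SNP {sid}: missing genotype for {individuals[i]}")
            col[i] = a + b
        ids.append(sid)
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        roles.append(role)
        columns.append(col)
    vcf.close()
    meta = pd.DataFrame({"id": ids, "chrom": chroms, "pos": positions, "role": roles})
    return GenotypeMatrix(genotypes=np.column_stack(columns), snp_meta=meta,
                          individual_ids=individuals)


def write_tsv(panel: GenotypeMatrix, path: str | Path, meta_path: str | Path) -> None:
    """Matrix TSV (rows = individuals, columns = SNP ids) plus a metadata TSV."""
    df = pd.DataFrame(panel.genotypes, index=panel.individual_ids,
                      columns=panel.snp_ids)
    df.to_csv(path, sep="\t", index_label="individual")
    panel.snp_meta.to_csv(meta_path, sep="\t", index=False)


def read_tsv(path: str | Path, meta_path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="individual")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"id": str, "chrom": str})
    if list(df.columns) != meta["id"].tolist():
        raise GenotypeError("matrix columns do not match the metadata SNP ids")
    return GenotypeMatrix(genotypes=df.to_numpy(dtype=np.int8), snp_meta=meta,
                          individual_ids=[str(i) for i in df.index])


def write_manifest(panel: GenotypeMatrix, path: str | Path) -> None:
    """Two-column TSV: SNP id, role."""
    panel.snp_meta[["id", "role"]].to_csv(path, sep="\t", index=False, header=False)


def read_manifest(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        sid, role = line.split("\t")
        out[sid] = role
    return out


# ---------------------------------------------------------------------------
# wire envelopes


def save_query(query: EncryptedQuery, path: str | Path, strict_privacy: bool = False) -> None:
    doc = {
        "protocol_version": PROTOCOL_VERSION,
        "key_fingerprint": query.key_fingerprint,
        "layout": query.layout.to_dict(),
        "n_individuals": query.n_individuals,
        "batch_sizes": query.batch_sizes,
        "bits": {f"{tag}|{pos}": [c.to_hex() for c in cts]
                 for (tag, pos), cts in query.bits.items()},
    }
    if not strict_privacy and query.individual_ids is not None:
        doc["individual_ids"] = query.individual_ids
    Path(path).write_text(json.dumps(doc))


def load_query(path: str | Path) -> EncryptedQuery:
    doc = json.loads(Path(path).read_text())
    layout = SlotLayout.from_dict(doc["layout"])
    bits = {}
    for key, hexes in doc["bits"].items():
        tag, pos = key.rsplit("|", 1)
        bits[(tag, int(pos))] = [Ciphertext.from_hex(h, layout) for h in hexes]
    return EncryptedQuery(
        bits=bits,
        layout=layout,
        n_individuals=doc["n_individuals"],
        batch_sizes=list(doc["batch_sizes"]),
        key_fingerprint=doc["key_fingerprint"],
        individual_ids=doc.get("individual_ids"),
    )


def save_result(result: EncryptedResult, path: str | Path) -> None:
    doc = {
        "protocol_version": PROTOCOL_VERSION,
        "key_fingerprint": result.key_fingerprint,
        "layout": result.layout.to_dict(),
        "n_individuals": result.n_individuals,
        "batch_sizes": result.batch_sizes,
        "target_ids": result.target_ids,
        "scores": {target: [[c.to_hex() for c in batch] for batch in per_class]
                   for target, per_class in result.scores.items()},
    }
    Path(path).write_text(json.dumps(doc))


def load_result(path: str | Path) -> EncryptedResult:
    doc = json.loads(Path(path).read_text())
    layout = SlotLayout.from_dict(doc["layout"])
    scores = {target: [[Ciphertext.from_hex(h, layout) for h in batch]
                       for batch in per_class]
              for target, per_class in doc["scores"].items()}
    return EncryptedResult(
        scores=scores,
        layout=layout,
        n_individuals=doc["n_individuals"],
        batch_sizes=list(doc["batch_sizes"]),
        key_fingerprint=doc["key_fingerprint"],
        target_ids=list(doc["target_ids"]),
    )


# ---------------------------------------------------------------------------
# predictions


def write_predictions_tsv(pred: PredictionTable, path: str | Path) -> None:
    df = pd.DataFrame(pred.genotypes, index=pred.individual_ids,
                      columns=pred.target_ids)
    df.to_csv(path, sep="\t", index_label="individual")


def write_predictions_vcf(pred: PredictionTable, path: str | Path,
                          snp_meta: Optional[pd.DataFrame] = None) -> None:
    """GT-only VCF of imputed genotypes (positions from ``snp_meta`` if given)."""
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Imputed genotype">',
    ]
    meta_by_id = {}
    if snp_meta is not None:
        meta_by_id = {row["id"]: row for _, row in snp_meta.iterrows()}
        for chrom in dict.fromkeys(str(row["chrom"]) for row in meta_by_id.values()):
            lines.append(f"##contig=<ID={chrom}>")
    else:
        lines.append("##contig=<ID=1>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += list(pred.individual_ids)
    lines.append("\t".join(header))
    for j, tid in enumerate(pred.target_ids):
        if tid in meta_by_id:
            row_meta = meta_by_id[tid]
            chrom, pos = str(row_meta["chrom"]), str(int(row_meta["pos"]))
        else:
            chrom, pos = "1", str(j + 1)
        row = [chrom, pos, tid, "A", "G", ".", "PASS", ".", "GT"]
        row += gt_strings[pred.genotypes[:, j]].tolist()
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
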