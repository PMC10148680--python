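"""Genotype file input: PLINK 1 binary filesets and VCF.

Variants are yielded one at a time as :class:`VariantRecord` with genotypes
coded as alternative-allele dosage classes 0/1/2 (-1 missing), matching the
convention of :mod:`poirot.stat_core`.  Only biallelic sites are usable by
the covariance test; multi-allelic VCF records are skipped with a warning.

The PLINK reader/writer handles the standard SNP-major .bed layout (magic
bytes 6c 1b 01, two bits per genotype packed four samples per byte) with
companion .bim/.fam text files; genotypes are reported as counts of the
.bim A1 allele, which is treated as the alternative allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["VariantRecord", "read_genotypes", "read_plink", "read_vcf", "write_plink"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes -> A1 dosage: 00 -> 2 (A1 hom), 01 -> missing,
# 10 -> 1 (het), 11 -> 0 (A2 hom)
_CODE_MAP = np.array([2, -1, 1, 0], dtype=np.int8)
_BYTE_LUT = np.array(
    [[_CODE_MAP[(byte >> (2 * i)) & 0b11] for i in range(4)] for byte in range(256)],
    dtype=np.int8,
)
_PACK_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant and its per-sample genotype vector."""

    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: np.ndarray  # int8, 0/1/2 alt dosage, -1 missing

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("position must be 1-based (>= 1)")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")


def read_plink(prefix: str | Path) -> Iterator[VariantRecord]:
    """Iterate variants of a PLINK 1 .bed/.bim/.fam fileset in file order."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n = len(fam)
    nbytes = (n + 3) // 4
    with open(bed_path, "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(
                f"{bed_path}: bad magic bytes {magic!r} at offset 0; not a SNP-major PLINK .bed file"
            )
        for _, row in bim.iterrows():
            raw = fh.read(nbytes)
            if len(raw) != nbytes:
                raise ValueError(f"{bed_path}: truncated at variant {row['id']}")
            codes = _BYTE_LUT[np.frombuffer(raw, dtype=np.uint8)].reshape(-1)[:n]
            yield VariantRecord(
                id=row["id"], chrom=row["chrom"], pos=int(row["pos"]),
                ref=row["a2"], alt=row["a1"], genotypes=codes.copy(),
            )


def write_plink(prefix: str | Path, variants: list[VariantRecord],
                sample_ids: list[str] | None = None) -> None:
    """Write a small SNP-major .bed/.bim/.fam fileset (testing / export)."""
    prefix = Path(prefix)
    n = len(variants[0].genotypes)
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(n)]
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.alt}\t{v.ref}\n")
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for v in variants:
            g = np.asarray(v.genotypes)
            padded = np.full(((n + 3) // 4) * 4, -1, dtype=np.int8)
            padded[:n] = g
            out = bytearray()
            for chunk in padded.reshape(-1, 4):
                byte = 0
                for i, code in enumerate(chunk):
                    byte |= _PACK_CODE[int(code)] << (2 * i)
                out.append(byte)
            fh.write(bytes(out))


def read_vcf(path: str | Path) -> Iterator[VariantRecord]:
    """Iterate biallelic variants of a VCF; multi-allelic sites are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    gt_map = np.array([0, 1, -1, 2], dtype=np.int8)
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%d (%s)", rec.CHROM, rec.POS, rec.ID)
            continue
        codes = gt_map[np.asarray(rec.gt_types)]
        yield VariantRecord(
            id=rec.ID or f"{rec.CHROM}:{rec.POS}", chrom=str(rec.CHROM),
            pos=int(rec.POS), ref=rec.REF, alt=rec.ALT[0], genotypes=codes,
        )


def read_genotypes(path: str | Path, format: str | None = None) -> Iterator[VariantRecord]:
    """Dispatch to the PLINK or VCF reader.

    ``format`` is 'plink_bed' or 'vcf'; when omitted it is inferred from
    the file suffix (.bed -> PLINK, .vcf/.vcf.gz -> VCF).
    """
    path = Path(path)
    if format is None:
        if path.suffix == ".bed" or path.with_suffix(".bed").exists():
            format = "plink_bed"
        elif path.name.endswith((".vcf", ".vcf.gz")):
            format = "vcf"
        else:
            raise ValueError(f"cannot infer genotype format from {path}")
    if format == "plink_bed":
        return read_plink(path.with_suffix("") if path.suffix == ".bed" else path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")
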