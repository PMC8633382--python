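"""Readers and writers for PLINK binary genotype files and delimited tables.

Only the SNP-major binary layout (mode byte ``0x01``) is supported. Genotypes
are decoded to A1-allele dosages (the allele in the fifth ``.bim`` column), so
a dosage of 2 means homozygous A1. Variant blocks are read through a memory
map, which keeps whole-genome scans from materialising the full matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BED_MAGIC = bytes([0x6C, 0x1B])
BED_MODE_SNP_MAJOR = 0x01

# Two-bit genotype codes, SNP-major: 00 -> hom A1 (2), 01 -> missing,
# 10 -> het (1), 11 -> hom A2 (0). Samples occupy bit pairs low-to-high.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}

_BYTE_LUT = np.empty((256, 4), dtype=np.float64)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]


class PlinkFormatError(ValueError):
    """Malformed .bed/.bim/.fam content."""


class AlignmentError(ValueError):
    """Sample identifiers in a table do not overlap the .fam samples."""


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    id: str
    bp: int
    a1: str
    a2: str


@dataclass(frozen=True)
class SampleRecord:
    fid: str
    iid: str


@dataclass
class GenotypeBlock:
    """A contiguous slice of variants: ``dosage`` is variants x samples with
    values in {0, 1, 2, nan}; sample order equals the .fam order."""

    dosage: np.ndarray
    variant_index_range: tuple[int, int]


def read_bim(path: str | Path) -> list[VariantRecord]:
    """Parse a .bim file (chrom, id, cM, bp, A1, A2) preserving line order."""
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise PlinkFormatError(
                    f"{path}: line {lineno} has {len(fields)} columns, expected 6"
                )
            chrom, vid, _cm, bp, a1, a2 = fields
            if not vid:
                raise PlinkFormatError(f"{path}: line {lineno} has empty variant id")
            try:
                bp_val = int(bp)
            except ValueError as exc:
                raise PlinkFormatError(
                    f"{path}: line {lineno} has non-integer position {bp!r}"
                ) from exc
            if bp_val < 1:
                raise PlinkFormatError(f"{path}: line {lineno} has position < 1")
            records.append(VariantRecord(chrom, vid, bp_val, a1, a2))
    return records


def read_fam(path: str | Path) -> list[SampleRecord]:
    """Parse a .fam file; only FID/IID are retained."""
    samples: list[SampleRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise PlinkFormatError(
                    f"{path}: line {lineno} has fewer than 2 columns"
                )
            key = (fields[0], fields[1])
            if key in seen:
                raise PlinkFormatError(f"{path}: duplicate sample {key} at line {lineno}")
            seen.add(key)
            samples.append(SampleRecord(*key))
    return samples


class BedFile:
    """Memory-mapped access to a SNP-major .bed file.

    Parameters
    ----------
    path : path to the .bed file
    n_samples : number of samples (rows of the .fam file)
    n_variants : number of variants (rows of the .bim file)
    """

    def __init__(self, path: str | Path, n_samples: int, n_variants: int):
        self.path = Path(path)
        self.n_samples = int(n_samples)
        self.n_variants = int(n_variants)
        self._bytes_per_variant = (self.n_samples + 3) // 4
        with open(self.path, "rb") as fh:
            header = fh.read(3)
        if len(header) < 3 or header[:2] != BED_MAGIC:
            raise PlinkFormatError(f"{self.path}: missing PLINK .bed magic bytes")
        if header[2] != BED_MODE_SNP_MAJOR:
            raise PlinkFormatError(
                f"{self.path}: mode byte 0x{header[2]:02x}; only SNP-major (0x01) supported"
            )
        expected = 3 + self._bytes_per_variant * self.n_variants
        actual = self.path.stat().st_size
        if actual < expected:
            raise PlinkFormatError(
                f"{self.path}: file has {actual} bytes, expected at least {expected}"
            )
        self._mmap = np.memmap(self.path, dtype=np.uint8, mode="r", offset=3)

    def read_block(self, variant_indices: Sequence[int] | range) -> GenotypeBlock:
        """Decode a block of variants to dosages (variants x samples)."""
        idx = np.asarray(variant_indices, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_variants):
            raise IndexError(
                f"variant index out of range [0, {self.n_variants}) for {self.path}"
            )
        bpv = self._bytes_per_variant
        raw = self._mmap[: bpv * self.n_variants].reshape(self.n_variants, bpv)
        packed = np.asarray(raw[idx])
        dosage = _BYTE_LUT[packed].reshape(idx.size, bpv * 4)[:, : self.n_samples]
        if isinstance(variant_indices, range):
            rng = (variant_indices.start, variant_indices.stop)
        else:
            rng = (int(idx.min(initial=0)), int(idx.max(initial=-1)) + 1)
        return GenotypeBlock(dosage=dosage, variant_index_range=rng)


def read_genotype_block(
    bed_path: str | Path,
    n_samples: int,
    variant_indices: Sequence[int] | range,
    n_variants: int | None = None,
) -> GenotypeBlock:
    """One-shot convenience wrapper around :class:`BedFile`."""
    if n_variants is None:
        idx = np.asarray(variant_indices, dtype=np.int64)
        n_variants = int(idx.max(initial=-1)) + 1
    return BedFile(bed_path, n_samples, n_variants).read_block(variant_indices)


def write_bed(path: str | Path, dosage: np.ndarray) -> None:
    """Write a variants x samples dosage matrix ({0,1,2,nan}) as SNP-major .bed."""
    dosage = np.asarray(dosage, dtype=np.float64)
    m, n = dosage.shape
    bpv = (n + 3) // 4
    codes = np.empty((m, bpv * 4), dtype=np.uint8)
    codes[:] = 0b00  # pad bit-pairs; ignored on read
    block = np.full((m, n), 0b01, dtype=np.uint8)  # default missing
    for value, code in _DOSAGE_TO_CODE.items():
        block[dosage == value] = code
    codes[:, :n] = block
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    )
    with open(path, "wb") as fh:
        fh.write(BED_MAGIC + bytes([BED_MODE_SNP_MAJOR]))
        fh.write(packed.astype(np.uint8).tobytes())


def write_bim(path: str | Path, variants: Sequence[VariantRecord]) -> None:
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.bp}\t{v.a1}\t{v.a2}\n")


def write_fam(path: str | Path, samples: Sequence[SampleRecord]) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(f"{s.fid}\t{s.iid}\t0\t0\t0\t-9\n")


def read_table(
    path: str | Path,
    fam_samples: Sequence[SampleRecord],
    value_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a delimited phenotype/covariate table aligned to the .fam order.

    The delimiter is auto-detected among tab/comma/whitespace. Samples are
    keyed by (FID, IID) when both columns are present, otherwise by IID; rows
    not present in the .fam are dropped (count logged) and samples absent from
    the table get all-missing rows. Non-numeric cells become NaN.
    """
    df = pd.read_csv(path, sep=None, engine="python", na_values=["NA", "na", "NaN"])
    cols = {c.lower(): c for c in df.columns}
    if "fid" in cols and "iid" in cols:
        key = list(zip(df[cols["fid"]].astype(str), df[cols["iid"]].astype(str)))
        fam_keys = [(s.fid, s.iid) for s in fam_samples]
        id_cols = {cols["fid"], cols["iid"]}
    elif "iid" in cols:
        key = list(df[cols["iid"]].astype(str))
        fam_keys = [s.iid for s in fam_samples]
        id_cols = {cols["iid"]}
    else:
        raise AlignmentError(f"{path}: no IID (or FID/IID) column found in header")

    if value_columns is None:
        value_columns = [c for c in df.columns if c not in id_cols]
    values = df[list(value_columns)].apply(pd.to_numeric, errors="coerce")
    values.index = pd.Index(key)
    values = values[~values.index.duplicated(keep="first")]

    overlap = values.index.intersection(pd.Index(fam_keys))
    if len(overlap) == 0:
        raise AlignmentError(f"{path}: no sample IDs overlap the .fam file")
    n_dropped = len(values) - len(overlap)
    if n_dropped:
        logger.info("%s: dropped %d rows not present in .fam", path, n_dropped)
    aligned = values.reindex(pd.Index(fam_keys))
    aligned.index = range(len(fam_keys))
    return aligned
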