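"""Genotype I/O in the standard SNP-array dialects.

Supported on read: PLINK text (PED/MAP), PLINK binary (BED/BIM/FAM,
SNP-major) and uncompressed/bgzipped VCF 4.x (GT field only, bi-allelic
sites). Supported on write: PLINK text, PLINK binary and plain-text VCF.
Population labels travel in the PED/FAM family column.

Loading never reorders samples; markers are always returned sorted by
(chromosome, position) with the genotype columns permuted to match.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, MarkerMap

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# 2-bit PLINK BED codes -> genotype codes (00 hom A1, 01 missing, 10 het, 11 hom A2)
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


class PlinkFormatError(ValueError):
    """Structural or format problem in a PLINK file."""


class VcfFormatError(ValueError):
    """Structural or format problem in a VCF file."""


def _sort_markers(
    calls: np.ndarray, frame: pd.DataFrame
) -> tuple[np.ndarray, MarkerMap]:
    mm = MarkerMap(frame)
    order = mm.sort_order()
    return calls[:, order], mm.subset(order)


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a PED/MAP pair.

    Alleles per marker are assigned in first-seen order over samples
    (``allele1`` = first non-missing allele encountered), and genotype codes
    count copies of ``allele2``. A third allele at a marker is an error.
    """
    map_frame = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm", "position_bp"],
        dtype={"chromosome": str, "marker_id": str},
    )
    n_markers = len(map_frame)

    sample_ids: list[str] = []
    populations: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise PlinkFormatError(
                    f"PED line {lineno}: expected {6 + 2 * n_markers} fields "
                    f"(6 + 2 per marker), got {len(fields)}"
                )
            populations.append(fields[0])
            sample_ids.append(fields[1])
            allele_rows.append(fields[6:])

    n_samples = len(sample_ids)
    calls = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    allele1 = np.full(n_markers, "0", dtype=object)
    allele2 = np.full(n_markers, "0", dtype=object)

    for j in range(n_markers):
        a1, a2 = "0", "0"
        for i in range(n_samples):
            x, y = allele_rows[i][2 * j], allele_rows[i][2 * j + 1]
            if x == "0" or y == "0":
                continue
            for a in (x, y):
                if a == a1 or a == a2:
                    continue
                if a1 == "0":
                    a1 = a
                elif a2 == "0":
                    a2 = a
                else:
                    raise PlinkFormatError(
                        f"marker {map_frame['marker_id'].iloc[j]!r}: more than "
                        f"two alleles observed ({a1}, {a2}, {a})"
                    )
            calls[i, j] = (x == a2) + (y == a2)
        allele1[j], allele2[j] = a1, a2

    frame = pd.DataFrame(
        {
            "marker_id": map_frame["marker_id"],
            "chromosome": map_frame["chromosome"],
            "position_bp": map_frame["position_bp"].astype(np.int64),
            "allele1": allele1,
            "allele2": allele2,
        }
    )
    calls, mm = _sort_markers(calls, frame)
    return GenotypeMatrix(calls, sample_ids, populations), mm


def write_plink_text(gm: GenotypeMatrix, mm: MarkerMap, prefix: str | Path) -> tuple[Path, Path]:
    """Write a PED/MAP pair; returns the two paths."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    f = mm.frame
    with open(map_path, "w") as fh:
        for row in f.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}\n")
    a1 = f["allele1"].to_numpy()
    a2 = f["allele2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            out = [gm.populations[i], sid, "0", "0", "0", "-9"]
            row = gm.calls[i]
            for j in range(gm.n_markers):
                c = row[j]
                if c == MISSING:
                    out += ["0", "0"]
                else:
                    if (c < 2 and a1[j] == "0") or (c > 0 and a2[j] == "0"):
                        raise PlinkFormatError(
                            f"marker {f['marker_id'].iloc[j]!r}: allele unknown "
                            "('0') but required to encode a genotype"
                        )
                    pair = [a1[j], a1[j]] if c == 0 else ([a1[j], a2[j]] if c == 1 else [a2[j], a2[j]])
                    out += pair
            fh.write(" ".join(out) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM)
# ---------------------------------------------------------------------------

def read_plink_binary(
    bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a SNP-major BED/BIM/FAM triple."""
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm", "position_bp", "allele1", "allele2"],
        dtype={"chromosome": str, "marker_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    n_markers, n_samples = len(bim), len(fam)
    if n_markers == 0:
        raise PlinkFormatError("BIM contains no markers")
    if n_samples == 0:
        raise PlinkFormatError("FAM contains no samples")

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError("BED magic bytes 0x6C 0x1B missing")
    if raw[2:3] != _BED_SNP_MAJOR:
        raise PlinkFormatError("BED is not in SNP-major mode")
    bytes_per_snp = (n_samples + 3) // 4
    expected = 3 + bytes_per_snp * n_markers
    if len(raw) != expected:
        raise PlinkFormatError(
            f"BED truncated or oversized: {len(raw)} bytes, expected {expected}"
        )
    block = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_markers, bytes_per_snp)
    # unpack 2-bit fields, least-significant pair first
    two_bit = (block[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 0b11
    codes = _BED_DECODE[two_bit.reshape(n_markers, -1)[:, :n_samples]]
    calls = np.ascontiguousarray(codes.T)

    frame = bim.drop(columns=["cm"])
    calls, mm = _sort_markers(calls, frame)
    return GenotypeMatrix(calls, fam["iid"].tolist(), fam["fid"].tolist()), mm


def write_plink_binary(gm: GenotypeMatrix, mm: MarkerMap, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write a SNP-major BED/BIM/FAM triple; population label -> FAM family id."""
    if gm.n_markers == 0:
        raise PlinkFormatError("refusing to write an empty marker set")
    if gm.n_markers != mm.n_markers:
        raise ValueError("genotype matrix and marker map disagree on marker count")
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    with open(bim_path, "w") as fh:
        for row in mm.frame.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.marker_id}\t0\t{row.position_bp}\t"
                f"{row.allele1}\t{row.allele2}\n"
            )
    with open(fam_path, "w") as fh:
        for pop, sid in zip(gm.populations, gm.sample_ids):
            fh.write(f"{pop}\t{sid}\t0\t0\t0\t-9\n")

    n_samples, n_markers = gm.n_samples, gm.n_markers
    enc = np.empty(4, dtype=np.uint8)  # indexed by code+1
    for code, bits in _BED_ENCODE.items():
        enc[code + 1] = bits
    two_bit = enc[gm.calls.T.astype(np.int16) + 1]  # (markers, samples)
    pad = (-n_samples) % 4
    if pad:
        two_bit = np.concatenate(
            [two_bit, np.zeros((n_markers, pad), dtype=np.uint8)], axis=1
        )
    two_bit = two_bit.reshape(n_markers, -1, 4)
    packed = (
        two_bit[:, :, 0]
        | (two_bit[:, :, 1] << 2)
        | (two_bit[:, :, 2] << 4)
        | (two_bit[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    vcf_path: str | Path, populations: Mapping[str, str] | None = None
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read GT genotypes from a VCF; multi-allelic sites are skipped with a
    warning. REF maps to allele1, ALT to allele2. Population labels come from
    the optional ``populations`` mapping (default ``"unknown"``)."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    if "FORMAT=<ID=GT" not in vcf.raw_header:
        raise VcfFormatError("VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError("VCF has no sample columns")

    rows = []
    columns = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        columns.append(gt)
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multi-allelic site(s)", stacklevel=2)
    if not rows:
        raise VcfFormatError("VCF contains no usable bi-allelic sites")

    calls = np.column_stack(columns).astype(np.int8)
    frame = pd.DataFrame(
        rows, columns=["marker_id", "chromosome", "position_bp", "allele1", "allele2"]
    )
    calls, mm = _sort_markers(calls, frame)
    pops = [populations.get(s, "unknown") if populations else "unknown" for s in samples]
    return GenotypeMatrix(calls, samples, pops), mm


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, mm: MarkerMap, path: str | Path) -> Path:
    """Write genotypes as an uncompressed VCF 4.2 with GT only."""
    path = Path(path)
    f = mm.frame
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohscan\n")
        for chrom in dict.fromkeys(f["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, row in enumerate(f.itertuples(index=False)):
            ref = row.allele1 if row.allele1 != "0" else "N"
            alt = row.allele2 if row.allele2 != "0" else "N"
            gts = "\t".join(_VCF_GT[int(c)] for c in gm.calls[:, j])
            fh.write(
                f"{row.chromosome}\t{row.position_bp}\t{row.marker_id}\t{ref}\t{alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )
    return path
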