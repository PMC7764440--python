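"""Core in-memory containers shared by every analysis stage.

Genotypes are held as an ``individuals x markers`` matrix of small integer
codes counting copies of ``allele2`` (the PLINK convention):

====  =========================
code  meaning
====  =========================
0     homozygous allele1
1     heterozygous
2     homozygous allele2
-1    missing call
====  =========================

Marker coordinates are 1-based inclusive base pairs on the reference the
genotypes were mapped to (ARS-UCD1.2 for the cattle chips this package was
written around); BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Missing-genotype code.
MISSING: int = -1

#: Cattle autosome labels; everything else (X, Y, MT, contigs) is flagged by QC.
CATTLE_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 30))

#: Autosomal genome length covered by the 150K chip used as the default
#: denominator of F_ROH on real cattle data, in bp.
L_AUT_BP: int = 2_487_082_459

#: ROH length classes in bp: left-closed, right-open intervals.
LENGTH_CLASS_EDGES_BP: tuple[int, ...] = (
    0,
    2_000_000,
    4_000_000,
    8_000_000,
    16_000_000,
)
LENGTH_CLASS_LABELS: tuple[str, ...] = ("<2Mb", "2-4Mb", "4-8Mb", "8-16Mb", ">16Mb")

_VALID_CODES = frozenset({MISSING, 0, 1, 2})


def chromosome_sort_key(label: str) -> tuple[int, float | str, str]:
    """Natural chromosome ordering: numeric labels first, then lexical."""
    s = str(label)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


def classify_length(length_bp: int) -> str:
    """Assign an ROH length (bp) to its class; intervals are [lo, hi)."""
    if length_bp < 0:
        raise ValueError("negative ROH length")
    idx = int(np.searchsorted(LENGTH_CLASS_EDGES_BP, length_bp, side="right")) - 1
    return LENGTH_CLASS_LABELS[idx]


class MarkerMap:
    """Per-marker chromosome, position and alleles.

    Wraps a :class:`pandas.DataFrame` with columns ``marker_id``,
    ``chromosome`` (text labels), ``position_bp`` (1-based int), ``allele1``,
    ``allele2`` (single characters, ``"0"`` when unknown).
    """

    REQUIRED = ("marker_id", "chromosome", "position_bp", "allele1", "allele2")

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        missing_cols = [c for c in self.REQUIRED if c not in frame.columns]
        if missing_cols:
            raise ValueError(f"marker map missing columns: {missing_cols}")
        frame = frame.loc[:, list(self.REQUIRED)].reset_index(drop=True).copy()
        frame["marker_id"] = frame["marker_id"].astype(str)
        frame["chromosome"] = frame["chromosome"].astype(str)
        frame["position_bp"] = frame["position_bp"].astype(np.int64)
        frame["allele1"] = frame["allele1"].astype(str)
        frame["allele2"] = frame["allele2"].astype(str)
        self.frame = frame
        if validate:
            self._validate()

    def _validate(self) -> None:
        ids = self.frame["marker_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker_id: {dup!r}")
        for chrom, sub in self.frame.groupby("chromosome", sort=False):
            pos = np.sort(sub["position_bp"].to_numpy())
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.frame)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.frame["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.frame["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.frame["position_bp"].to_numpy()

    def unique_chromosomes(self) -> list[str]:
        """Chromosome labels in natural order."""
        return sorted(set(self.frame["chromosome"]), key=chromosome_sort_key)

    # -- ordering --------------------------------------------------------
    def sort_order(self) -> np.ndarray:
        """Index array sorting markers by (natural chromosome, position)."""
        key = self.frame["chromosome"].map(chromosome_sort_key)
        tmp = pd.DataFrame(
            {"k": key, "pos": self.frame["position_bp"], "i": np.arange(len(self.frame))}
        )
        return tmp.sort_values(["k", "pos"], kind="mergesort")["i"].to_numpy()

    def is_position_sorted(self) -> bool:
        """True when every chromosome forms one contiguous, position-ascending block."""
        chroms = self.chromosomes
        pos = self.positions
        seen: set[str] = set()
        prev = None
        for i, c in enumerate(chroms):
            if c != prev:
                if c in seen:
                    return False
                seen.add(c)
                prev = c
            elif pos[i] <= pos[i - 1]:
                return False
        return True

    def chromosome_blocks(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, slice) blocks; requires a sorted map."""
        if not self.is_position_sorted():
            raise ValueError("marker map is not position-sorted per chromosome")
        chroms = self.chromosomes
        blocks: list[tuple[str, slice]] = []
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                blocks.append((chroms[start], slice(start, i)))
                start = i
        return blocks

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.frame.iloc[np.asarray(idx)], validate=False)

    def __len__(self) -> int:
        return self.n_markers

    def __repr__(self) -> str:
        return f"MarkerMap(n_markers={self.n_markers})"


def covered_autosome_length(marker_map: MarkerMap) -> int:
    """Genome length covered by the map: sum over chromosomes of
    (last - first SNP position + 1). The dataset-specific analogue of the
    chip-coverage constant used as the F_ROH denominator."""
    total = 0
    for _, sub in marker_map.frame.groupby("chromosome", sort=False):
        pos = sub["position_bp"]
        total += int(pos.max() - pos.min() + 1)
    return total


@dataclass
class GenotypeMatrix:
    """Genotype codes for a cohort: ``calls[i, j]`` is sample i at marker j."""

    calls: np.ndarray
    sample_ids: list[str]
    populations: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.populations = [str(p) for p in self.populations]
        if len(self.sample_ids) != self.calls.shape[0]:
            raise ValueError("sample_ids length does not match calls rows")
        if len(self.populations) != self.calls.shape[0]:
            raise ValueError("populations length does not match calls rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        bad = set(np.unique(self.calls)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes present: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def population_mask(self, population: str) -> np.ndarray:
        return np.asarray([p == population for p in self.populations])

    def unique_populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.calls[idx].copy(),
            [self.sample_ids[i] for i in idx],
            [self.populations[i] for i in idx],
        )

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.calls[:, idx].copy(), list(self.sample_ids), list(self.populations)
        )

    def population_of(self) -> Mapping[str, str]:
        return dict(zip(self.sample_ids, self.populations))

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix(n_samples={self.n_samples}, n_markers={self.n_markers}, "
            f"populations={self.unique_populations()})"
        )


@dataclass(frozen=True)
class RohSegment:
    """One run of homozygosity: 1-based inclusive positions of its first and
    last SNP."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_class(self) -> str:
        return classify_length(self.length_bp)


def segments_to_frame(segments: Iterable[RohSegment]) -> pd.DataFrame:
    """Tabulate segments (one row each) with derived length and class."""
    rows = [
        (s.sample_id, s.chromosome, s.start_bp, s.end_bp, s.n_snps, s.length_bp, s.length_class)
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "chromosome",
            "start_bp",
            "end_bp",
            "n_snps",
            "length_bp",
            "length_class",
        ],
    )


def allele_frequencies(gm: GenotypeMatrix, sample_mask: np.ndarray | None = None) -> np.ndarray:
    """Allele2 frequency per marker from non-missing calls.

    Markers with no called genotype in the (sub)cohort get frequency NaN.
    """
    calls = gm.calls if sample_mask is None else gm.calls[np.asarray(sample_mask)]
    valid = calls >= 0
    n_alleles = 2 * valid.sum(axis=0)
    alt = np.where(valid, calls, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return freq
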