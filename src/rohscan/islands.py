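"""ROH islands: per-marker occurrence, top-1% thresholding, interval
construction, cross-population sharing and gene/QTL annotation.

Within one population, a marker's *occurrence* is the number of individuals
whose ROH cover its position. The markers in the top 1% of occurrence
("TOP SNPs", ties at the rank threshold included) delimit the ROH islands:
consecutive TOP SNPs on a chromosome are merged into one interval while the
inter-SNP distance stays within a merge gap (default 1 Mb, mirroring the
ROH gap rule). Islands are then intersected with user-supplied gene and QTL
intervals (>= 1 bp overlap, half-open arithmetic internally, 1-based
inclusive coordinates on output).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import ceil
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import MarkerMap, RohSegment


@dataclass
class OccurrenceProfile:
    """Per-marker ROH occurrence counts within one population."""

    counts: np.ndarray  # aligned with the marker map
    population: str
    n_individuals: int

    def __post_init__(self) -> None:
        if (self.counts < 0).any() or (self.counts > self.n_individuals).any():
            raise ValueError("occurrence counts must lie in [0, population size]")


@dataclass(frozen=True)
class IslandRegion:
    population: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_top_snps: int
    max_occurrence: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class AnnotatedIsland:
    island: IslandRegion
    genes: list[str] = field(default_factory=list)
    qtls: list[tuple[str, str]] = field(default_factory=list)  # (name, class)


def occurrence_profile(
    segments: Iterable[RohSegment],
    mm: MarkerMap,
    sample_ids: Sequence[str],
    population: str,
) -> OccurrenceProfile:
    """Count, for every marker, the individuals among ``sample_ids`` with an
    ROH covering its position (an individual counts once per marker; ROH of
    one individual on one chromosome are non-overlapping by construction)."""
    sample_set = set(sample_ids)
    blocks = dict(mm.chromosome_blocks())
    positions = mm.positions
    counts = np.zeros(mm.n_markers, dtype=np.int64)
    diff = np.zeros(mm.n_markers + 1, dtype=np.int64)
    for seg in segments:
        if seg.sample_id not in sample_set:
            continue
        sl = blocks.get(seg.chromosome)
        if sl is None:
            raise ValueError(f"segment chromosome {seg.chromosome!r} not in map")
        lo = sl.start + int(np.searchsorted(positions[sl], seg.start_bp, side="left"))
        hi = sl.start + int(np.searchsorted(positions[sl], seg.end_bp, side="right"))
        diff[lo] += 1
        diff[hi] -= 1
    counts = np.cumsum(diff[:-1])
    return OccurrenceProfile(counts=counts, population=population, n_individuals=len(sample_set))


def top_snp_threshold(
    profile: OccurrenceProfile, top_fraction: float = 0.01
) -> tuple[int, np.ndarray]:
    """Occurrence threshold at rank ``ceil(top_fraction * M)`` and the marker
    indices at or above it (ties included, so the set may exceed the
    nominal fraction). An all-zero profile returns an empty set."""
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    counts = profile.counts
    m = len(counts)
    if m == 0 or counts.max() == 0:
        warnings.warn("occurrence profile is all zero; no TOP SNPs", stacklevel=2)
        return 0, np.array([], dtype=int)
    rank = ceil(top_fraction * m)
    threshold = int(np.sort(counts)[::-1][rank - 1])
    if threshold == 0:
        warnings.warn(
            "top-fraction rank falls in the zero-occurrence tail; every marker "
            "qualifies",
            stacklevel=2,
        )
    top = np.flatnonzero(counts >= threshold)
    if threshold > 0 and len(top) == m:
        warnings.warn(
            "every marker ties at the occurrence threshold; TOP-SNP set covers "
            "the whole map",
            stacklevel=2,
        )
    return threshold, top


def build_islands(
    top_snps: np.ndarray,
    profile: OccurrenceProfile,
    mm: MarkerMap,
    merge_gap_bp: int = 1_000_000,
) -> list[IslandRegion]:
    """Merge position-sorted TOP SNPs of one chromosome into maximal
    intervals while consecutive TOP SNPs are at most ``merge_gap_bp`` apart;
    region bounds are the first/last TOP SNP positions."""
    top_snps = np.asarray(sorted(top_snps))
    if len(top_snps) == 0:
        return []
    chroms = mm.chromosomes
    positions = mm.positions
    counts = profile.counts

    islands: list[IslandRegion] = []
    run: list[int] = [int(top_snps[0])]
    for idx in top_snps[1:]:
        idx = int(idx)
        prev = run[-1]
        same = chroms[idx] == chroms[prev]
        if same and positions[idx] - positions[prev] <= merge_gap_bp:
            run.append(idx)
        else:
            islands.append(_close_island(run, profile.population, chroms, positions, counts))
            run = [idx]
    islands.append(_close_island(run, profile.population, chroms, positions, counts))
    return islands


def _close_island(run, population, chroms, positions, counts) -> IslandRegion:
    return IslandRegion(
        population=population,
        chromosome=str(chroms[run[0]]),
        start_bp=int(positions[run[0]]),
        end_bp=int(positions[run[-1]]),
        n_top_snps=len(run),
        max_occurrence=int(counts[run].max()),
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _feature_trees(features: pd.DataFrame, label: str) -> dict[str, IntervalTree]:
    required = {"chromosome", "start_bp", "end_bp", "name"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"{label} features missing columns: {sorted(missing)}")
    trees: dict[str, IntervalTree] = {}
    for row_no, row in enumerate(features.itertuples(index=False), start=1):
        start, end = int(row.start_bp), int(row.end_bp)
        if end < start:
            raise ValueError(f"{label} feature line {row_no}: end < start")
        cls = getattr(row, "feature_class", "")
        trees.setdefault(str(row.chromosome), IntervalTree()).addi(
            start - 1, end, (str(row.name), str(cls))  # to 0-based half-open
        )
    return trees


def intersect_annotation(
    islands: Sequence[IslandRegion],
    genes: pd.DataFrame | None = None,
    qtls: pd.DataFrame | None = None,
) -> list[AnnotatedIsland]:
    """Attach gene names and (name, class) QTLs overlapping each island by at
    least 1 bp. Feature frames need columns ``chromosome``, ``start_bp``,
    ``end_bp`` (1-based inclusive), ``name`` and optionally
    ``feature_class``."""
    gene_trees = _feature_trees(genes, "gene") if genes is not None else {}
    qtl_trees = _feature_trees(qtls, "QTL") if qtls is not None else {}

    out: list[AnnotatedIsland] = []
    for isl in islands:
        lo, hi = isl.start_bp - 1, isl.end_bp  # half-open query
        g_hits = sorted({iv.data[0] for iv in gene_trees.get(isl.chromosome, IntervalTree())[lo:hi]})
        q_hits = sorted({iv.data for iv in qtl_trees.get(isl.chromosome, IntervalTree())[lo:hi]})
        out.append(AnnotatedIsland(island=isl, genes=g_hits, qtls=q_hits))
    return out


def qtl_class_counts(annotated: Sequence[AnnotatedIsland]) -> pd.DataFrame:
    """Count annotated QTLs per (population, class) over all islands."""
    rows: dict[tuple[str, str], int] = {}
    for ann in annotated:
        for _, cls in ann.qtls:
            key = (ann.island.population, cls)
            rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [{"population": p, "qtl_class": c, "count": n} for (p, c), n in sorted(rows.items())]
    )


# ---------------------------------------------------------------------------
# Cross-population sharing
# ---------------------------------------------------------------------------

@dataclass
class SharingResult:
    """Venn-style partition of genes and interval intersections of islands."""

    gene_partition: dict[frozenset, set]  # exact membership subset -> genes
    shared_regions: dict[frozenset, list[tuple[str, int, int]]]  # subset (>=2 pops)

    def partition_counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.gene_partition.items()}


def _intersect_interval_lists(
    a: list[tuple[str, int, int]], b: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    out = []
    for chrom_a, s_a, e_a in a:
        for chrom_b, s_b, e_b in b:
            if chrom_a != chrom_b:
                continue
            s, e = max(s_a, s_b), min(e_a, e_b)
            if s <= e:
                out.append((chrom_a, s, e))
    return sorted(out)


def cross_population_sharing(
    islands_by_pop: Mapping[str, Sequence[IslandRegion]],
    genes_by_pop: Mapping[str, Iterable[str]] | None = None,
) -> SharingResult:
    """Region sharing by interval intersection over every subset of >= 2
    populations, and a Venn partition of per-population gene sets (each gene
    assigned to the exact subset of populations listing it)."""
    pops = list(islands_by_pop)
    if len(pops) < 2:
        raise ValueError("need at least two populations")

    ivals = {
        p: [(i.chromosome, i.start_bp, i.end_bp) for i in islands_by_pop[p]] for p in pops
    }
    shared: dict[frozenset, list[tuple[str, int, int]]] = {}
    for r in range(2, len(pops) + 1):
        for combo in combinations(pops, r):
            acc = ivals[combo[0]]
            for p in combo[1:]:
                acc = _intersect_interval_lists(acc, ivals[p])
            shared[frozenset(combo)] = acc

    partition: dict[frozenset, set] = {}
    if genes_by_pop is not None:
        gene_sets = {p: set(genes_by_pop.get(p, ())) for p in pops}
        union = set().union(*gene_sets.values())
        for gene in union:
            members = frozenset(p for p in pops if gene in gene_sets[p])
            partition.setdefault(members, set()).add(gene)
    return SharingResult(gene_partition=partition, shared_regions=shared)


# ---------------------------------------------------------------------------
# Feature file readers
# ---------------------------------------------------------------------------

def read_bed_features(path, feature_class_column: int | None = None) -> pd.DataFrame:
    """Read BED intervals (0-based half-open on disk) into the 1-based
    inclusive feature frame; column 4 is the name, and an optional extra
    column index (0-based) supplies ``feature_class``."""
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if raw.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    frame = pd.DataFrame(
        {
            "chromosome": raw[0].astype(str),
            "start_bp": raw[1].astype(np.int64) + 1,
            "end_bp": raw[2].astype(np.int64),
            "name": raw[3].astype(str) if raw.shape[1] > 3 else [f"feat{i}" for i in range(len(raw))],
        }
    )
    if feature_class_column is not None:
        frame["feature_class"] = raw[feature_class_column].astype(str)
    return frame


def read_gff3_features(path, feature_type: str = "gene") -> pd.DataFrame:
    """Extract intervals of one feature type from a GFF3 file (coordinates
    are already 1-based inclusive); the name comes from the ``Name``,
    ``gene_name`` or ``ID`` attribute, in that order."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type(feature_type):
        name = (
            feat.attributes.get("Name", [None])[0]
            or feat.attributes.get("gene_name", [None])[0]
            or feat.id
        )
        rows.append(
            {
                "chromosome": str(feat.seqid),
                "start_bp": int(feat.start),
                "end_bp": int(feat.end),
                "name": str(name),
            }
        )
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "name"])


def islands_to_frame(islands: Sequence[IslandRegion]) -> pd.DataFrame:
    """Islands as a 1-based inclusive table (Chr/Start/End/Length shape)."""
    return pd.DataFrame(
        [
            {
                "population": i.population,
                "chromosome": i.chromosome,
                "start_bp": i.start_bp,
                "end_bp": i.end_bp,
                "length_bp": i.length_bp,
                "n_top_snps": i.n_top_snps,
                "max_occurrence": i.max_occurrence,
            }
            for i in islands
        ],
        columns=[
            "population",
            "chromosome",
            "start_bp",
            "end_bp",
            "length_bp",
            "n_top_snps",
            "max_occurrence",
        ],
    )
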