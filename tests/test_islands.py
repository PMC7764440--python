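"""Occurrence profiles, TOP-SNP thresholding, island building, annotation."""

import numpy as np
import pandas as pd
import pytest

from rohscan import (
    IslandRegion,
    MarkerMap,
    RohSegment,
    build_islands,
    cross_population_sharing,
    intersect_annotation,
    occurrence_profile,
    top_snp_threshold,
)
from rohscan.islands import OccurrenceProfile, read_bed_features

from conftest import make_marker_map


def multi_chrom_map(markers_per_chrom=50, chroms=("1", "2"), spacing=100_000):
    frames = []
    for c in chroms:
        f = make_marker_map(markers_per_chrom, chromosome=c, spacing_bp=spacing).frame
        frames.append(f)
    return MarkerMap(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Occurrence
# ---------------------------------------------------------------------------

def test_no_segments_gives_all_zero():
    mm = multi_chrom_map()
    prof = occurrence_profile([], mm, ["a", "b"], "P")
    assert prof.counts.sum() == 0


def test_single_segment_counts_once():
    mm = multi_chrom_map()
    pos = mm.positions
    seg = RohSegment("a", "1", int(pos[10]), int(pos[20]), 11)
    prof = occurrence_profile([seg], mm, ["a", "b", "c", "d", "e"], "P")
    assert np.array_equal(np.flatnonzero(prof.counts), np.arange(10, 21))
    assert prof.counts.max() == 1


def test_occurrence_matches_brute_force():
    rng = np.random.default_rng(91)
    mm = multi_chrom_map(markers_per_chrom=80, chroms=("1", "2", "3"))
    pos, chroms = mm.positions, mm.chromosomes
    samples = [f"s{i}" for i in range(12)]
    segs = []
    for _ in range(60):
        s = samples[rng.integers(12)]
        c = str(rng.integers(1, 4))
        a, b = sorted(rng.integers(1, 8_000_000, size=2))
        segs.append(RohSegment(s, c, int(a), int(b) + 1, 1))
    # keep per-individual/chromosome segments non-overlapping, as detect_roh guarantees
    pruned = []
    seen = {}
    for seg in segs:
        key = (seg.sample_id, seg.chromosome)
        if any(not (seg.end_bp < a or b < seg.start_bp) for a, b in seen.get(key, [])):
            continue
        seen.setdefault(key, []).append((seg.start_bp, seg.end_bp))
        pruned.append(seg)
    prof = occurrence_profile(pruned, mm, samples, "P")
    brute = np.zeros(mm.n_markers, dtype=int)
    for j in range(mm.n_markers):
        for s in samples:
            if any(
                seg.sample_id == s
                and seg.chromosome == chroms[j]
                and seg.start_bp <= pos[j] <= seg.end_bp
                for seg in pruned
            ):
                brute[j] += 1
    assert np.array_equal(prof.counts, brute)


def test_counts_bounded_by_population_size():
    with pytest.raises(ValueError, match="population size"):
        OccurrenceProfile(counts=np.array([3]), population="P", n_individuals=2)


# ---------------------------------------------------------------------------
# TOP-SNP threshold
# ---------------------------------------------------------------------------

def test_rank_arithmetic_on_distinct_profile():
    counts = np.arange(200)[::-1].copy()  # distinct occurrences 199..0
    prof = OccurrenceProfile(counts=counts, population="P", n_individuals=200)
    threshold, top = top_snp_threshold(prof, 0.01)  # ceil(2) = rank 2
    assert threshold == 198
    assert len(top) == 2


def test_ties_at_threshold_are_included():
    counts = np.full(200, 7)
    prof = OccurrenceProfile(counts=counts, population="P", n_individuals=10)
    with pytest.warns(UserWarning, match="tie"):
        threshold, top = top_snp_threshold(prof, 0.01)
    assert threshold == 7 and len(top) == 200  # uniform profile: all tied


def test_full_fraction_returns_all_markers():
    counts = np.array([5, 1, 3, 0, 2])
    prof = OccurrenceProfile(counts=counts, population="P", n_individuals=6)
    with pytest.warns(UserWarning, match="zero-occurrence"):
        threshold, top = top_snp_threshold(prof, 1.0)
    assert threshold == 0 and len(top) == 5


def test_all_zero_profile_is_empty_with_warning():
    prof = OccurrenceProfile(counts=np.zeros(100, dtype=int), population="P", n_individuals=5)
    with pytest.warns(UserWarning, match="all zero"):
        threshold, top = top_snp_threshold(prof)
    assert threshold == 0 and len(top) == 0


# ---------------------------------------------------------------------------
# Island construction
# ---------------------------------------------------------------------------

def island_inputs(top_idx, counts=None):
    mm = multi_chrom_map(markers_per_chrom=50, spacing=100_000)
    c = np.zeros(mm.n_markers, dtype=int) if counts is None else counts
    c[np.asarray(top_idx, dtype=int)] = np.maximum(c[np.asarray(top_idx, dtype=int)], 1)
    prof = OccurrenceProfile(counts=c, population="P", n_individuals=10)
    return mm, prof


def test_single_top_snp_degenerate_region():
    mm, prof = island_inputs([7])
    isl = build_islands(np.array([7]), prof, mm)
    assert len(isl) == 1
    assert isl[0].start_bp == isl[0].end_bp == int(mm.positions[7])
    assert isl[0].n_top_snps == 1


def test_two_far_top_snps_make_two_regions():
    mm, prof = island_inputs([0, 21])  # 2.1 Mb apart at 100 kb spacing
    isl = build_islands(np.array([0, 21]), prof, mm)
    assert len(isl) == 2


def test_merge_respects_chromosome_and_gap():
    mm, prof = island_inputs([10, 12, 14, 49, 50, 51])
    isl = build_islands(np.array([10, 12, 14, 49, 50, 51]), prof, mm)
    # 49 is on chromosome 1; 50, 51 start chromosome 2
    assert [(i.chromosome, i.n_top_snps) for i in isl] == [("1", 3), ("1", 1), ("2", 2)]
    # every TOP SNP lies in exactly one region
    assert sum(i.n_top_snps for i in isl) == 6


def test_hand_merged_profile():
    mm, prof = island_inputs([5, 6, 7], counts=np.zeros(100, dtype=int))
    prof.counts[5:8] = [3, 9, 4]
    isl = build_islands(np.array([5, 6, 7]), prof, mm)
    assert isl[0].max_occurrence == 9
    assert isl[0].start_bp == int(mm.positions[5]) and isl[0].end_bp == int(mm.positions[7])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def region(chrom, start, end, pop="P"):
    return IslandRegion(pop, chrom, start, end, n_top_snps=1, max_occurrence=1)


def test_abutting_feature_does_not_overlap():
    isl = region("1", 1_000, 2_000)
    genes = pd.DataFrame(
        {"chromosome": ["1"], "start_bp": [2_001], "end_bp": [3_000], "name": ["G"]}
    )
    out = intersect_annotation([isl], genes=genes)
    assert out[0].genes == []


def test_contained_and_single_bp_overlap_reported():
    isl = region("1", 1_000, 2_000)
    genes = pd.DataFrame(
        {
            "chromosome": ["1", "1", "2"],
            "start_bp": [1_200, 2_000, 1_200],
            "end_bp": [1_300, 2_500, 1_300],
            "name": ["inside", "edge", "wrong_chrom"],
        }
    )
    out = intersect_annotation([isl], genes=genes)
    assert out[0].genes == ["edge", "inside"]


def test_malformed_feature_rejected_with_line():
    genes = pd.DataFrame(
        {"chromosome": ["1"], "start_bp": [500], "end_bp": [400], "name": ["bad"]}
    )
    with pytest.raises(ValueError, match="line 1"):
        intersect_annotation([region("1", 1, 10)], genes=genes)


def test_annotation_matches_brute_force():
    rng = np.random.default_rng(92)
    islands = [
        region(str(rng.integers(1, 4)), *sorted(rng.integers(1, 5_000_000, 2)))
        for _ in range(30)
    ]
    feats = pd.DataFrame(
        {
            "chromosome": [str(c) for c in rng.integers(1, 4, 40)],
            "start_bp": (s := rng.integers(1, 5_000_000, 40)),
            "end_bp": s + rng.integers(0, 200_000, 40),
            "name": [f"g{i}" for i in range(40)],
        }
    )
    out = intersect_annotation(islands, genes=feats)
    for isl, ann in zip(islands, out):
        brute = sorted(
            r["name"]
            for _, r in feats.iterrows()
            if r["chromosome"] == isl.chromosome
            and not (r["end_bp"] < isl.start_bp or isl.end_bp < r["start_bp"])
        )
        assert ann.genes == brute


def test_qtl_classes_carried_through():
    isl = region("1", 1_000, 2_000)
    qtls = pd.DataFrame(
        {
            "chromosome": ["1"],
            "start_bp": [1_500],
            "end_bp": [1_600],
            "name": ["QTL1"],
            "feature_class": ["Milk"],
        }
    )
    out = intersect_annotation([isl], qtls=qtls)
    assert out[0].qtls == [("QTL1", "Milk")]


def test_bed_reader_converts_to_one_based(tmp_path):
    bed = tmp_path / "g.bed"
    bed.write_text("1\t999\t2000\tG1\n2\t0\t100\tG2\n")
    feats = read_bed_features(bed)
    assert feats.loc[0, "start_bp"] == 1_000 and feats.loc[0, "end_bp"] == 2_000
    assert feats.loc[1, "start_bp"] == 1


# ---------------------------------------------------------------------------
# Sharing
# ---------------------------------------------------------------------------

def test_identical_island_sets_fully_shared():
    isl = [region("1", 100, 200, "A")]
    res = cross_population_sharing(
        {"A": isl, "B": [region("1", 100, 200, "B")]},
        {"A": {"g1"}, "B": {"g1"}},
    )
    assert res.shared_regions[frozenset({"A", "B"})] == [("1", 100, 200)]
    assert res.gene_partition[frozenset({"A", "B"})] == {"g1"}


def test_disjoint_sets_share_nothing():
    res = cross_population_sharing(
        {"A": [region("1", 100, 200, "A")], "B": [region("2", 100, 200, "B")]},
        {"A": {"g1"}, "B": {"g2"}},
    )
    assert res.shared_regions[frozenset({"A", "B"})] == []
    assert frozenset({"A", "B"}) not in res.gene_partition


def test_three_population_venn_partition():
    genes = {
        "A": {"g1", "g2", "g3", "g5"},
        "B": {"g1", "g2", "g4"},
        "C": {"g1", "g6"},
    }
    islands = {p: [region("1", 1, 10, p)] for p in genes}
    res = cross_population_sharing(islands, genes)
    counts = res.partition_counts()
    assert counts[frozenset({"A", "B", "C"})] == 1  # g1
    assert counts[frozenset({"A", "B"})] == 1  # g2
    assert counts[frozenset({"A"})] == 2  # g3, g5
    # partition sizes sum to the union
    assert sum(counts.values()) == len(set.union(*genes.values()))


def test_pairwise_region_intersection_clips_bounds():
    res = cross_population_sharing(
        {"A": [region("1", 100, 500, "A")], "B": [region("1", 300, 900, "B")]},
    )
    assert res.shared_regions[frozenset({"A", "B"})] == [("1", 300, 500)]
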