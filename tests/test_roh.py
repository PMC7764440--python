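"""ROH scanner: threshold boundaries, oracle equivalence, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rohscan import (
    MISSING,
    MarkerMap,
    RohParams,
    RohSegment,
    chromosome_coverage,
    detect_roh,
    summarize_roh,
)
from rohscan.types import classify_length, segments_to_frame

from conftest import make_genotypes, make_marker_map


def single_row(calls, positions, chromosome="1"):
    mm = MarkerMap(
        pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(len(positions))],
                "chromosome": chromosome,
                "position_bp": positions,
                "allele1": "A",
                "allele2": "G",
            }
        )
    )
    gm = make_genotypes(np.asarray([calls], dtype=np.int8))
    return gm, mm


def enumerate_maximal_runs(calls, positions, params):
    """Independent oracle: enumerate every maximal window of consecutive
    markers that are all non-missing homozygotes with internal gaps within
    the limit, then apply the SNP-count and length floors."""
    n = len(positions)
    out = []
    valid = (np.asarray(calls) == 0) | (np.asarray(calls) == 2)
    for a in range(n):
        if not valid[a]:
            continue
        # maximal start: not extendable to the left
        if a > 0 and valid[a - 1] and positions[a] - positions[a - 1] <= params.max_gap_bp:
            continue
        b = a
        while (
            b + 1 < n
            and valid[b + 1]
            and positions[b + 1] - positions[b] <= params.max_gap_bp
        ):
            b += 1
        n_snps = b - a + 1
        length = positions[b] - positions[a] + 1
        if n_snps >= params.min_snps and length >= params.min_length_bp:
            out.append((int(positions[a]), int(positions[b]), n_snps))
    return out


# ---------------------------------------------------------------------------
# Threshold boundaries (the five-rule set)
# ---------------------------------------------------------------------------

def test_length_floor_rejects_999kb():
    # 60 homozygous SNPs spanning 999,000 bp
    pos = 1 + np.round(np.linspace(0, 998_999, 60)).astype(int)
    gm, mm = single_row([0] * 60, pos)
    assert detect_roh(gm, mm) == []


def test_snp_floor_rejects_59_markers():
    pos = 1 + np.round(np.linspace(0, 1_199_999, 59)).astype(int)
    gm, mm = single_row([2] * 59, pos)
    assert detect_roh(gm, mm) == []


def test_exact_thresholds_accepted():
    pos = 1 + np.round(np.linspace(0, 999_999, 60)).astype(int)
    gm, mm = single_row([0] * 60, pos)
    segs = detect_roh(gm, mm)
    assert len(segs) == 1 and segs[0].n_snps == 60 and segs[0].length_bp == 1_000_000


def test_single_heterozygote_splits_and_kills_run():
    """120 homozygotes over 1.5 Mb with one het in the middle: both halves
    fail the 60-SNP floor, matching the exhaustive enumeration."""
    pos = 1 + np.round(np.linspace(0, 1_499_999, 121)).astype(int)
    calls = [0] * 121
    calls[60] = 1
    gm, mm = single_row(calls, pos)
    assert detect_roh(gm, mm) == []
    assert enumerate_maximal_runs(calls, pos, RohParams()) == []


def test_gap_over_1mb_breaks_run():
    spacing = 17_000
    pos = np.cumsum([1] + [spacing] * 124)
    pos[66:] += 1_000_100 - spacing  # gap of 1,000,100 bp between markers 65 and 66
    gm, mm = single_row([0] * 125, pos)
    segs = detect_roh(gm, mm)
    # right side restarts but holds only 59 markers; left part qualifies alone
    assert len(segs) == 1
    assert segs[0].n_snps == 66 and segs[0].end_bp == int(pos[65])


def test_gap_exactly_1mb_allowed():
    spacing = 17_000
    pos = np.cumsum([1] + [spacing] * 130)
    pos[66:] += 1_000_000 - spacing
    gm, mm = single_row([0] * 131, pos)
    segs = detect_roh(gm, mm)
    assert len(segs) == 1 and segs[0].n_snps == 131


def test_missing_call_breaks_run():
    pos = 1 + 17_000 * np.arange(130)
    calls = [0] * 130
    calls[65] = MISSING
    gm, mm = single_row(calls, pos)
    segs = detect_roh(gm, mm)
    assert [s.n_snps for s in segs] == [65, 64]


def test_unsorted_map_is_a_contract_error():
    gm, mm = single_row([0] * 10, 1 + 17_000 * np.arange(10))
    shuffled = MarkerMap(mm.frame.iloc[::-1], validate=False)
    with pytest.raises(ValueError, match="sorted"):
        detect_roh(gm, shuffled)


def test_lenient_het_allowance_not_supported():
    with pytest.raises(NotImplementedError):
        RohParams(max_het=1)


# ---------------------------------------------------------------------------
# Oracle equivalence and monotonicity
# ---------------------------------------------------------------------------

def random_instance(rng, n=None, het_rate=0.04, missing_rate=0.03):
    n = n or int(rng.integers(50, 400))
    gaps = rng.exponential(17_000, size=n - 1).astype(np.int64) + 1
    big = rng.random(n - 1) < 0.02
    gaps[big] += 1_500_000
    pos = np.concatenate([[1], 1 + np.cumsum(gaps)])
    hom = 1.0 - het_rate - missing_rate
    calls = rng.choice(
        [0, 2, 1, MISSING], size=n, p=[hom * 0.52, hom * 0.48, het_rate, missing_rate]
    )
    return calls.astype(np.int8), pos


@pytest.mark.parametrize("params", [RohParams(), RohParams(min_snps=10, min_length_bp=150_000, max_gap_bp=200_000)])
def test_scanner_matches_enumeration_on_random_instances(params):
    rng = np.random.default_rng(61)
    for _ in range(200):
        calls, pos = random_instance(rng)
        gm, mm = single_row(calls, pos)
        got = {(s.start_bp, s.end_bp, s.n_snps) for s in detect_roh(gm, mm, params)}
        want = set(enumerate_maximal_runs(calls, pos, params))
        assert got == want


@settings(max_examples=60, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 80), st.integers(1, 10))
def test_tightening_thresholds_never_adds_segments(seed, min_snps, factor):
    rng = np.random.default_rng(seed)
    calls, pos = random_instance(rng, n=120)
    gm, mm = single_row(calls, pos)
    loose = RohParams(min_snps=min_snps, min_length_bp=100_000, max_gap_bp=200_000 * factor)
    tight = RohParams(min_snps=min_snps + 5, min_length_bp=150_000, max_gap_bp=200_000 * factor)
    assert len(detect_roh(gm, mm, tight)) <= len(detect_roh(gm, mm, loose))
    # widening the gap allowance merges runs, so the segment *count* is not
    # monotone, but the set of covered markers can only grow
    narrower_gap = RohParams(min_snps=min_snps, min_length_bp=100_000, max_gap_bp=100_000 * factor)

    def covered(params):
        out = set()
        for s in detect_roh(gm, mm, params):
            out |= set(range(int(np.searchsorted(pos, s.start_bp)), int(np.searchsorted(pos, s.end_bp, side="right"))))
        return out

    assert covered(narrower_gap) <= covered(loose)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def test_length_class_boundaries():
    assert classify_length(1_999_999) == "<2Mb"
    assert classify_length(2_000_000) == "2-4Mb"
    assert classify_length(4_000_000) == "4-8Mb"  # exactly 4 Mb -> [4, 8)
    assert classify_length(16_000_000) == ">16Mb"


def test_single_segment_summary():
    seg = RohSegment("s0", "1", 1_000_001, 3_500_000, 150)
    summary = summarize_roh([seg], {"s0": "popA"})
    row = summary.population_stats.iloc[0]
    assert row["total_roh"] == 1 and row["mean_length_bp"] == 2_500_000
    cls = summary.class_stats
    assert cls.loc[cls["length_class"] == "2-4Mb", "count"].iloc[0] == 1


def test_hand_built_summary_matches_hand_computation():
    segs = [
        RohSegment("a", "1", 1, 1_200_000, 70),
        RohSegment("a", "2", 1, 2_500_000, 100),
        RohSegment("a", "2", 5_000_000, 10_000_000, 200),
        RohSegment("b", "1", 1, 17_000_000, 400),
        RohSegment("b", "3", 1, 1_100_000, 61),
    ]
    pops = {"a": "P", "b": "P", "c": "P"}  # c has zero ROH
    summary = summarize_roh(segs, pops)
    ind = summary.individual_stats.set_index("sample_id")
    assert ind.loc["a", "n_roh"] == 3
    assert ind.loc["a", "total_length_bp"] == 1_200_000 + 2_500_000 + 5_000_001
    assert ind.loc["c", "n_roh"] == 0
    row = summary.population_stats.iloc[0]
    assert row["total_roh"] == 5
    assert row["min_count"] == 0 and row["max_count"] == 3
    assert row["max_length_bp"] == 17_000_000
    freqs = summary.class_stats["frequency"]
    assert freqs.sum() == pytest.approx(1.0)


def test_chromosome_coverage_conserves_totals():
    segs = [
        RohSegment("a", "1", 1, 1_200_000, 70),
        RohSegment("a", "2", 1, 2_500_000, 100),
        RohSegment("b", "2", 1, 3_000_000, 90),
    ]
    mm = make_marker_map(10)  # chromosome "1" only
    frame = mm.frame.copy()
    extra = []
    for chrom in ("2", "3"):
        f2 = frame.copy()
        f2["chromosome"] = chrom
        f2["marker_id"] = f2["marker_id"] + chrom
        extra.append(f2)
    mm3 = MarkerMap(pd.concat([frame] + extra, ignore_index=True))
    cov = chromosome_coverage(segs, mm3).set_index("chromosome")
    assert cov["n_roh"].sum() == 3
    assert cov.loc["3", "n_roh"] == 0 and cov.loc["3", "frequency"] == 0
    assert cov["frequency"].sum() == pytest.approx(1.0)
    assert cov.loc["2", "mean_length_bp"] == pytest.approx((2_500_000 + 3_000_000) / 2)
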