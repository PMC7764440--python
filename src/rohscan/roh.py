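"""Rule-based Runs-of-Homozygosity detection and summaries.

A run of homozygosity (ROH) is scored per individual and chromosome over the
position-sorted markers: a run extends while the call is a non-missing
homozygote and the distance to the previous marker in the run is at most
``max_gap_bp``; any heterozygote, missing call, over-gap or chromosome end
closes it. Runs with at least ``min_snps`` markers and spanning at least
``min_length_bp`` (first-to-last SNP, 1-based inclusive) are emitted. No
heterozygous or missing calls are tolerated inside a run, and no LD pruning
is applied beforehand — short, common runs are instead excluded by the
1 Mb / 60-SNP floor.

Defaults encode the standard medium-density chip rule set: minimum 1000 kb
and 60 consecutive homozygous SNPs, maximum inter-SNP gap 1000 kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    LENGTH_CLASS_LABELS,
    GenotypeMatrix,
    MarkerMap,
    RohSegment,
    segments_to_frame,
)


@dataclass(frozen=True)
class RohParams:
    """Thresholds of the scanning rule (all in bp / marker counts)."""

    min_length_bp: int = 1_000_000
    min_snps: int = 60
    max_het: int = 0
    max_missing: int = 0
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("min_length_bp", "min_snps", "max_het", "max_missing", "max_gap_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_het or self.max_missing:
            raise NotImplementedError(
                "only the strict rule (no heterozygote, no missing call inside "
                "a run) is implemented"
            )


def detect_roh(
    gm: GenotypeMatrix, mm: MarkerMap, params: RohParams = RohParams()
) -> list[RohSegment]:
    """Scan every individual for ROH; the marker map must already be
    position-sorted (an unsorted map is a contract error, never silently
    re-sorted). Output is ordered by (sample, chromosome, start)."""
    if gm.n_markers != mm.n_markers:
        raise ValueError("genotype matrix and marker map disagree on marker count")
    blocks = mm.chromosome_blocks()  # raises on unsorted input
    positions = mm.positions

    segments: list[RohSegment] = []
    for i, sample_id in enumerate(gm.sample_ids):
        row = gm.calls[i]
        hom = (row == 0) | (row == 2)
        for chrom, sl in blocks:
            idx = np.flatnonzero(hom[sl]) + sl.start
            if len(idx) == 0:
                continue
            pos = positions
            if len(idx) == 1:
                runs = [idx]
            else:
                gap_break = (pos[idx[1:]] - pos[idx[:-1]]) > params.max_gap_bp
                breaks = (np.diff(idx) != 1) | gap_break
                runs = np.split(idx, np.flatnonzero(breaks) + 1)
            for run in runs:
                n = len(run)
                if n < params.min_snps:
                    continue
                start, end = int(pos[run[0]]), int(pos[run[-1]])
                if end - start + 1 < params.min_length_bp:
                    continue
                segments.append(RohSegment(sample_id, chrom, start, end, n))
    return segments


@dataclass
class RohSummary:
    """Descriptive statistics of a segment set at three resolutions."""

    population_stats: pd.DataFrame  # per population
    individual_stats: pd.DataFrame  # per individual (zero-ROH individuals included)
    class_stats: pd.DataFrame  # per population x length class


def summarize_roh(
    segments: Iterable[RohSegment], populations: Mapping[str, str]
) -> RohSummary:
    """Summarize detected ROH per population, individual and length class.

    ``populations`` maps every cohort sample to its population so that
    individuals without any ROH contribute zero counts.
    """
    seg_frame = segments_to_frame(segments)
    unknown = set(seg_frame["sample_id"]) - set(populations)
    if unknown:
        raise KeyError(f"segments reference samples missing from mapping: {sorted(unknown)[:3]}")

    individuals = pd.DataFrame(
        {"sample_id": list(populations), "population": list(populations.values())}
    )
    per_ind = (
        seg_frame.groupby("sample_id")
        .agg(n_roh=("length_bp", "size"), total_length_bp=("length_bp", "sum"))
        .reset_index()
    )
    individual_stats = individuals.merge(per_ind, on="sample_id", how="left")
    for col in ("n_roh", "total_length_bp"):
        individual_stats[col] = (
            pd.to_numeric(individual_stats[col], errors="coerce").fillna(0).astype(np.int64)
        )
    with np.errstate(invalid="ignore"):
        individual_stats["mean_length_bp"] = np.where(
            individual_stats["n_roh"] > 0,
            individual_stats["total_length_bp"] / individual_stats["n_roh"].replace(0, 1),
            0.0,
        )

    rows = []
    pops = list(dict.fromkeys(populations.values()))
    seg_frame = seg_frame.assign(
        population=seg_frame["sample_id"].map(populations) if len(seg_frame) else []
    )
    for pop in pops:
        ind = individual_stats[individual_stats["population"] == pop]
        segs = seg_frame[seg_frame["population"] == pop] if len(seg_frame) else seg_frame
        rows.append(
            {
                "population": pop,
                "total_roh": int(ind["n_roh"].sum()),
                "min_count": int(ind["n_roh"].min()),
                "max_count": int(ind["n_roh"].max()),
                "mean_count": float(ind["n_roh"].mean()),
                "min_length_bp": int(segs["length_bp"].min()) if len(segs) else 0,
                "max_length_bp": int(segs["length_bp"].max()) if len(segs) else 0,
                "mean_length_bp": float(segs["length_bp"].mean()) if len(segs) else 0.0,
            }
        )
    population_stats = pd.DataFrame(rows)

    class_rows = []
    for pop in pops:
        segs = seg_frame[seg_frame["population"] == pop] if len(seg_frame) else seg_frame
        total = len(segs)
        for label in LENGTH_CLASS_LABELS:
            sub = segs[segs["length_class"] == label] if total else segs
            class_rows.append(
                {
                    "population": pop,
                    "length_class": label,
                    "count": len(sub),
                    "frequency": len(sub) / total if total else 0.0,
                    "mean_length_bp": float(sub["length_bp"].mean()) if len(sub) else 0.0,
                }
            )
    class_stats = pd.DataFrame(class_rows)
    return RohSummary(population_stats, individual_stats, class_stats)


def chromosome_coverage(
    segments: Iterable[RohSegment], mm: MarkerMap
) -> pd.DataFrame:
    """Per-chromosome ROH count, mean length and frequency (share of all
    ROH); chromosomes without segments report zeros."""
    seg_frame = segments_to_frame(segments)
    total = len(seg_frame)
    rows = []
    for chrom in mm.unique_chromosomes():
        sub = seg_frame[seg_frame["chromosome"] == chrom] if total else seg_frame
        rows.append(
            {
                "chromosome": chrom,
                "n_roh": len(sub),
                "mean_length_bp": float(sub["length_bp"].mean()) if len(sub) else 0.0,
                "frequency": len(sub) / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def segments_to_bed(segments: Sequence[RohSegment]) -> pd.DataFrame:
    """Segments as 0-based half-open BED records (name = sample id)."""
    frame = segments_to_frame(segments)
    return pd.DataFrame(
        {
            "chrom": frame["chromosome"],
            "start": frame["start_bp"] - 1,
            "end": frame["end_bp"],
            "name": frame["sample_id"],
        }
    )
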