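"""Marker/sample quality control and LD pruning.

The QC rule set mirrors standard SNP-chip practice for breed-diversity
studies: drop markers without a chromosomal position or outside the autosome
set, then drop samples with call rate <= the threshold, then drop markers
with call rate <= the threshold (call rate = fraction of non-missing calls;
"<= 0.90 deleted" is implemented as *keep if strictly greater*). The filter
order is fixed and the operation is idempotent on its own output.

LD pruning removes markers greedily so that no retained pair within a
50-marker sliding window (advancing 5 markers at a time over the currently
retained markers of a chromosome) has squared Pearson correlation of
genotype codes above the cutoff; of an offending pair the lower-MAF member
is dropped (tie: the later marker).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CATTLE_AUTOSOMES, GenotypeMatrix, MarkerMap, allele_frequencies


@dataclass
class QcReport:
    n_samples_in: int
    n_samples_out: int
    n_markers_in: int
    n_markers_out: int
    removed_samples: pd.DataFrame  # sample_id, call_rate
    removed_markers: pd.DataFrame  # marker_id, reason in {call_rate, no_position, non_autosomal}

    def __post_init__(self) -> None:
        if self.n_samples_in - len(self.removed_samples) != self.n_samples_out:
            raise ValueError("sample bookkeeping inconsistent")
        if self.n_markers_in - len(self.removed_markers) != self.n_markers_out:
            raise ValueError("marker bookkeeping inconsistent")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": ["samples", "markers"],
                "n_in": [self.n_samples_in, self.n_markers_in],
                "n_removed": [len(self.removed_samples), len(self.removed_markers)],
                "n_out": [self.n_samples_out, self.n_markers_out],
            }
        )


class EmptyAfterQcError(ValueError):
    """Raised when QC removes every sample or every marker."""


def qc_filter(
    gm: GenotypeMatrix,
    mm: MarkerMap,
    sample_cr_min: float = 0.90,
    marker_cr_min: float = 0.90,
    autosomes: tuple[str, ...] = CATTLE_AUTOSOMES,
) -> tuple[GenotypeMatrix, MarkerMap, QcReport]:
    """Apply position/autosome, sample call-rate and marker call-rate filters
    in that fixed order. Thresholds are exclusive: entities with call rate
    <= the minimum are deleted."""
    n_samples_in, n_markers_in = gm.n_samples, gm.n_markers
    autoset = set(autosomes)

    chroms = mm.chromosomes
    positions = mm.positions
    no_pos = positions < 1
    non_auto = ~np.isin(chroms, list(autoset)) & ~no_pos
    marker_keep = ~(no_pos | non_auto)

    removed_markers = [
        (mid, "no_position") for mid in mm.marker_ids[no_pos]
    ] + [(mid, "non_autosomal") for mid in mm.marker_ids[non_auto]]

    calls = gm.calls[:, marker_keep]
    if calls.shape[1] == 0:
        raise EmptyAfterQcError("no markers left after position/autosome filter")

    sample_cr = (calls >= 0).mean(axis=1)
    sample_keep = sample_cr > sample_cr_min
    removed_samples = [
        (gm.sample_ids[i], float(sample_cr[i]))
        for i in np.flatnonzero(~sample_keep)
    ]
    if not sample_keep.any():
        raise EmptyAfterQcError("no samples left after call-rate filter")

    calls = calls[sample_keep]
    marker_cr = (calls >= 0).mean(axis=0)
    cr_keep = marker_cr > marker_cr_min
    kept_idx = np.flatnonzero(marker_keep)
    removed_markers += [
        (mm.marker_ids[kept_idx[j]], "call_rate") for j in np.flatnonzero(~cr_keep)
    ]
    if not cr_keep.any():
        raise EmptyAfterQcError("no markers left after call-rate filter")

    final_marker_idx = kept_idx[cr_keep]
    out_gm = gm.subset_samples(np.flatnonzero(sample_keep)).subset_markers(final_marker_idx)
    out_mm = mm.subset(final_marker_idx)

    report = QcReport(
        n_samples_in=n_samples_in,
        n_samples_out=out_gm.n_samples,
        n_markers_in=n_markers_in,
        n_markers_out=out_gm.n_markers,
        removed_samples=pd.DataFrame(removed_samples, columns=["sample_id", "call_rate"]),
        removed_markers=pd.DataFrame(removed_markers, columns=["marker_id", "reason"]),
    )
    return out_gm, out_mm, report


def _pairwise_complete_r2(calls: np.ndarray) -> np.ndarray:
    """r^2 between all marker pairs of ``calls`` (samples x markers) using
    pairwise-complete observations; undefined pairs (no shared calls or zero
    variance) are returned as 0."""
    X = calls.astype(np.float64)
    V = X >= 0
    X0 = np.where(V, X, 0.0)
    Vf = V.astype(np.float64)
    n = Vf.T @ Vf
    sx = X0.T @ Vf  # sx[i, j] = sum of x_i over samples complete in (i, j)
    sxy = X0.T @ X0
    q = (X0 * X0).T @ Vf
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sx.T / n
        varx = q - sx * sx / n
        vary = q.T - sx.T * sx.T / n
        r2 = cov * cov / (varx * vary)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_prune(
    gm: GenotypeMatrix,
    mm: MarkerMap,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Greedy within-window LD pruning; returns the sorted integer indices of
    retained markers. The scan repeats per chromosome until no window holds a
    retained pair with r^2 > ``r2_max``."""
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if step_snps < 1:
        raise ValueError("step_snps must be >= 1")

    freq = allele_frequencies(gm)
    maf = np.minimum(np.nan_to_num(freq, nan=0.0), 1 - np.nan_to_num(freq, nan=1.0))
    keep = np.ones(gm.n_markers, dtype=bool)

    for _, sl in mm.chromosome_blocks():
        changed = True
        while changed:
            changed = False
            kept_idx = np.flatnonzero(keep[sl]) + sl.start
            if len(kept_idx) < 2:
                break
            for start in range(0, len(kept_idx), step_snps):
                w = kept_idx[start : start + window_snps]
                if len(w) < 2:
                    continue
                w = w[keep[w]]  # drop markers removed by an earlier window
                if len(w) < 2:
                    continue
                r2 = _pairwise_complete_r2(gm.calls[:, w])
                alive = np.ones(len(w), dtype=bool)
                for a in range(len(w)):
                    if not alive[a]:
                        continue
                    for b in range(a + 1, len(w)):
                        if not alive[b] or r2[a, b] <= r2_max:
                            continue
                        ma, mb = maf[w[a]], maf[w[b]]
                        victim = b if (mb < ma or mb == ma) else a
                        alive[victim] = False
                        keep[w[victim]] = False
                        changed = True
                        if victim == a:
                            break
    return np.flatnonzero(keep)


def audit_ld_prune(
    gm: GenotypeMatrix,
    mm: MarkerMap,
    kept: np.ndarray,
    window_snps: int = 50,
    r2_max: float = 0.5,
) -> int:
    """Count retained pairs within any ``window_snps`` consecutive retained
    markers of a chromosome whose r^2 exceeds the cutoff (0 on a valid
    pruning)."""
    kept = np.asarray(kept)
    violations = 0
    for _, sl in mm.chromosome_blocks():
        w_all = kept[(kept >= sl.start) & (kept < sl.stop)]
        # blocks of 2w overlapping by w cover every pair at rank distance < w
        for start in range(0, max(len(w_all) - 1, 1), window_snps):
            w = w_all[start : start + 2 * window_snps]
            if len(w) < 2:
                continue
            r2 = _pairwise_complete_r2(gm.calls[:, w])
            a, b = np.triu_indices(len(w), k=1)
            close = (b - a) < window_snps
            violations += int((r2[a[close], b[close]] > r2_max).sum())
    return violations
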