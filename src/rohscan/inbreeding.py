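"""Genomic inbreeding coefficients.

Two complementary estimators are provided:

* ``F_ROH = L_ROH / L_AUT`` — the share of the SNP-covered autosomal genome
  an individual carries inside runs of homozygosity, where ``L_ROH`` is the
  summed length of the individual's ROH and ``L_AUT`` the autosomal length
  covered by markers (default: the 150K-chip constant 2,487,082,459 bp; for
  simulated genomes pass the map's own covered length).
* excess-homozygosity ``F = (O - E) / (L - E)`` per individual, with ``O``
  the observed homozygote count, ``L`` the individual's non-missing marker
  count and ``E = sum_j (1 - 2 p_j (1 - p_j))`` the homozygote count
  expected under Hardy-Weinberg at the cohort allele frequencies, summed
  over the individual's non-missing markers. F ranges -1..+1; 0 means
  Hardy-Weinberg proportions.

All ROH lengths are accumulated as exact integer base pairs, and each
reported ratio is a single correctly-rounded division, so F_ROH partitions
(by chromosome or by length class) sum exactly to the total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import (
    L_AUT_BP,
    LENGTH_CLASS_LABELS,
    GenotypeMatrix,
    RohSegment,
    allele_frequencies,
    segments_to_frame,
)


def f_roh(l_roh_bp: float, l_aut_bp: float = L_AUT_BP) -> float:
    """Genomic inbreeding from total ROH length: ``L_ROH / L_AUT``."""
    if l_aut_bp <= 0:
        raise ValueError("l_aut_bp must be positive")
    if l_roh_bp < 0:
        raise ValueError("l_roh_bp must be non-negative")
    return l_roh_bp / l_aut_bp


@dataclass
class RohInbreeding:
    """Per-sample F_ROH at total, length-class and chromosome resolution.

    The integer base-pair ledgers (``by_chromosome_bp``, ``by_class_bp``)
    partition ``l_roh_bp`` exactly; the ratio frames carry one rounding per
    entry.
    """

    table: pd.DataFrame  # sample_id, population, l_roh_bp, f_roh + class columns
    by_chromosome: pd.DataFrame  # samples x chromosomes (f_roh contributions)
    by_chromosome_bp: pd.DataFrame  # samples x chromosomes, integer bp
    by_class_bp: pd.DataFrame  # samples x length classes, integer bp
    l_aut_bp: float


def roh_inbreeding(
    segments: Iterable[RohSegment],
    populations: Mapping[str, str],
    l_aut_bp: float = L_AUT_BP,
) -> RohInbreeding:
    """Compute F_ROH per individual (individuals without ROH get 0)."""
    if l_aut_bp <= 0:
        raise ValueError("l_aut_bp must be positive")
    seg = segments_to_frame(segments)
    samples = list(populations)
    zeros = pd.Series(0, index=samples, dtype=np.int64)

    total = zeros.add(seg.groupby("sample_id")["length_bp"].sum(), fill_value=0).astype(np.int64)
    table = pd.DataFrame(
        {
            "sample_id": samples,
            "population": [populations[s] for s in samples],
            "l_roh_bp": total.loc[samples].to_numpy(),
        }
    )
    table["f_roh"] = table["l_roh_bp"] / l_aut_bp
    class_bp = {}
    for label in LENGTH_CLASS_LABELS:
        cls = seg[seg["length_class"] == label] if len(seg) else seg
        cls_len = zeros.add(cls.groupby("sample_id")["length_bp"].sum(), fill_value=0)
        class_bp[label] = cls_len.loc[samples].to_numpy().astype(np.int64)
        table[f"f_roh_{label}"] = class_bp[label] / l_aut_bp
    by_class_bp = pd.DataFrame(class_bp, index=samples)

    if len(seg):
        chrom_len = (
            seg.pivot_table(
                index="sample_id",
                columns="chromosome",
                values="length_bp",
                aggfunc="sum",
                fill_value=0,
            )
            .reindex(samples, fill_value=0)
            .astype(np.int64)
        )
    else:
        chrom_len = pd.DataFrame(index=samples)
    by_chromosome = chrom_len / l_aut_bp
    return RohInbreeding(
        table=table,
        by_chromosome=by_chromosome,
        by_chromosome_bp=chrom_len,
        by_class_bp=by_class_bp,
        l_aut_bp=l_aut_bp,
    )


def excess_homozygosity_f(
    gm: GenotypeMatrix, freqs: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-sample excess-homozygosity inbreeding coefficient.

    ``freqs`` are the allele frequencies defining Hardy-Weinberg expectation;
    by default they are computed from the matrix itself (pass per-population
    frequencies to measure departure within a breed). Missing calls are
    excluded from O, E and L of that sample. Samples with ``L == E`` (no
    information) are reported as F = 0 with ``degenerate=True``.
    """
    if freqs is None:
        freqs = allele_frequencies(gm)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (gm.n_markers,):
        raise ValueError("freqs length must equal the marker count")

    valid = gm.calls >= 0
    hom = (gm.calls == 0) | (gm.calls == 2)
    # per-marker expected homozygote probability; monomorphic markers give 1
    p_hom = 1.0 - 2.0 * freqs * (1.0 - freqs)
    p_hom = np.nan_to_num(p_hom, nan=1.0)

    obs = (hom & valid).sum(axis=1).astype(float)
    n_nonmissing = valid.sum(axis=1).astype(float)
    exp = valid @ p_hom

    denom = n_nonmissing - exp
    degenerate = np.isclose(denom, 0.0)
    f = np.where(degenerate, 0.0, (obs - exp) / np.where(degenerate, 1.0, denom))
    return pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "population": gm.populations,
            "obs_hom": obs.astype(np.int64),
            "exp_hom": exp,
            "n_nonmissing": n_nonmissing.astype(np.int64),
            "f": f,
            "degenerate": degenerate,
        }
    )


def population_inbreeding_summary(
    f_table: pd.DataFrame, roh_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-population min/max/mean of F and F_ROH plus mean observed and
    expected homozygote counts (one row per population)."""
    merged = f_table.merge(
        roh_table[["sample_id", "f_roh"]], on="sample_id", how="inner"
    )
    rows = []
    for pop, sub in merged.groupby("population", sort=False):
        rows.append(
            {
                "population": pop,
                "mean_obs_hom": float(sub["obs_hom"].mean()),
                "mean_exp_hom": float(sub["exp_hom"].mean()),
                "f_min": float(sub["f"].min()),
                "f_max": float(sub["f"].max()),
                "f_mean": float(sub["f"].mean()),
                "f_roh_min": float(sub["f_roh"].min()),
                "f_roh_max": float(sub["f_roh"].max()),
                "f_roh_mean": float(sub["f_roh"].mean()),
            }
        )
    return pd.DataFrame(rows)


def f_vs_froh_regression(
    f: pd.Series | np.ndarray,
    f_roh: pd.Series | np.ndarray,
    populations: Iterable[str],
) -> pd.DataFrame:
    """Ordinary least squares of F (y) on F_ROH (x) per population.

    Populations with zero variance in F_ROH are flagged (``degenerate``)
    with NaN coefficients; a constant response gives slope 0 and R^2 = 0.
    """
    frame = pd.DataFrame(
        {"f": np.asarray(f, float), "f_roh": np.asarray(f_roh, float), "population": list(populations)}
    )
    rows = []
    for pop, sub in frame.groupby("population", sort=False):
        if len(sub) < 3:
            raise ValueError(f"population {pop!r}: need at least 3 individuals")
        x = sub["f_roh"].to_numpy()
        y = sub["f"].to_numpy()
        if np.ptp(x) == 0:
            rows.append(
                {"population": pop, "slope": np.nan, "intercept": np.nan, "r2": np.nan, "degenerate": True}
            )
            continue
        if np.ptp(y) == 0:
            rows.append(
                {"population": pop, "slope": 0.0, "intercept": float(y[0]), "r2": 0.0, "degenerate": False}
            )
            continue
        res = sps.linregress(x, y)
        rows.append(
            {
                "population": pop,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r2": float(res.rvalue**2),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)
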