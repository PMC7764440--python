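"""Synthetic structured-population genotypes with ground truth.

The generator emulates the statistical structure a multi-breed SNP-array
analysis assumes: a handful of populations diverged from a common ancestral
gene pool at chosen F_ST levels, Mb-scale autozygous tracts planted into
individual genomes, and missing/heterozygote-error noise. Divergence follows
the Balding--Nichols model: for a marker with ancestral allele frequency
``p`` and a population at divergence ``F``, the population frequency is drawn
from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` (mean ``p``, variance ``p(1-p)F``) and
genotypes are ``Binomial(2, p_k)`` draws, i.e. within-population
Hardy--Weinberg.

Pairwise F_ST between populations ``k`` and ``l`` under this model is
``(F_k + F_l) / 2`` (Hudson sense), which is how a pairwise target matrix is
converted to per-population divergences.

Randomness: one integer seed feeds a :class:`numpy.random.SeedSequence`
whose children are consumed in a fixed, documented order (ancestral
frequencies, positions/alleles, per-population frequencies, genotypes), so a
fixed seed gives bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    allele_frequencies,
)

_NUCLEOTIDES = np.array(list("ACGT"))

# Default pairwise divergence targets: three breeds in the regime observed on
# alpine cattle (two pairs near 0.05, one near 0.02).
DEFAULT_FST_MATRIX = (
    (0.0, 0.019, 0.052),
    (0.019, 0.0, 0.050),
    (0.052, 0.050, 0.0),
)


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults are the desk-scale profile: 3 populations x 50 individuals and
    29 chromosomes x 700 markers (~20K markers) with ~19 kb marker spacing,
    the density of a 150K bovine chip, and pairwise divergence targets in
    the 0.02--0.05 band.
    """

    seed: int
    n_populations: int = 3
    n_per_population: Sequence[int] = (50, 50, 50)
    n_chromosomes: int = 29
    markers_per_chromosome: int = 700
    chromosome_length_bp: int = 13_300_000
    fst: float | Sequence[float] | Sequence[Sequence[float]] = DEFAULT_FST_MATRIX
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.002
    het_error_rate: float = 0.0
    population_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        if len(self.n_per_population) != self.n_populations:
            raise ValueError("n_per_population length must equal n_populations")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.het_error_rate < 1):
            raise ValueError("het_error_rate must be in [0, 1)")
        f = self.per_population_f()
        if np.any(f < 0) or np.any(f >= 1):
            raise ValueError("per-population divergence must lie in [0, 1)")
        if self.population_labels is not None and len(self.population_labels) != self.n_populations:
            raise ValueError("population_labels length must equal n_populations")

    def per_population_f(self) -> np.ndarray:
        """Per-population Balding--Nichols divergence derived from ``fst``.

        A scalar applies to every population; a length-k vector is used as
        is; a k x k pairwise matrix ``M`` is solved (least squares) under
        ``M[k, l] = (F_k + F_l) / 2``.
        """
        k = self.n_populations
        arr = np.asarray(self.fst, dtype=float)
        if arr.ndim == 0:
            return np.full(k, float(arr))
        if arr.ndim == 1:
            if len(arr) != k:
                raise ValueError("fst vector length must equal n_populations")
            return arr.copy()
        if arr.shape != (k, k):
            raise ValueError("fst matrix must be n_populations x n_populations")
        if k == 1:
            return np.zeros(1)
        pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
        design = np.zeros((len(pairs), k))
        target = np.zeros(len(pairs))
        for r, (a, b) in enumerate(pairs):
            design[r, a] = design[r, b] = 0.5
            target[r] = arr[a, b]
        sol, *_ = np.linalg.lstsq(design, target, rcond=None)
        return np.clip(sol, 0.0, None)

    def labels(self) -> list[str]:
        if self.population_labels is not None:
            return [str(p) for p in self.population_labels]
        return [f"pop{i + 1}" for i in range(self.n_populations)]


@dataclass(frozen=True)
class PlantedSegment:
    """Ground truth for one planted autozygous tract."""

    sample_id: str
    chromosome: str
    start_bp: int  # requested interval (bp, 1-based inclusive)
    end_bp: int
    first_marker: int  # global marker indices covered; -1 when empty
    last_marker: int
    n_markers: int

    @property
    def is_empty(self) -> bool:
        return self.n_markers == 0


@dataclass
class SimTruth:
    """Everything the generator knows that the analysis must rediscover."""

    per_population_f: np.ndarray
    ancestral_freqs: np.ndarray
    population_freqs: np.ndarray  # (k, m) realized Balding-Nichols draws
    population_labels: list[str]
    planted_segments: list[PlantedSegment] = field(default_factory=list)

    def planted_by_sample(self) -> dict[str, list[PlantedSegment]]:
        out: dict[str, list[PlantedSegment]] = {}
        for seg in self.planted_segments:
            out.setdefault(seg.sample_id, []).append(seg)
        return out


def _sample_positions(rng: np.random.Generator, n: int, length_bp: int) -> np.ndarray:
    """Distinct, sorted, 1-based positions uniform on [1, length_bp]."""
    if n > length_bp:
        raise ValueError("more markers requested than base pairs available")
    pos: np.ndarray = np.unique(rng.integers(1, length_bp + 1, size=n))
    while len(pos) < n:
        extra = rng.integers(1, length_bp + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:n] if len(pos) == n else np.sort(rng.choice(pos, n, replace=False))


def simulate_populations(config: SimConfig) -> tuple[GenotypeMatrix, MarkerMap, SimTruth]:
    """Draw a structured multi-population genotype dataset.

    Returns the genotype matrix (samples grouped by population), the
    position-sorted marker map and a :class:`SimTruth` recording the realized
    ancestral and per-population allele frequencies.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_anc, rng_map, rng_pop, rng_geno, rng_noise = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    m = config.n_chromosomes * config.markers_per_chromosome
    lo, hi = config.ancestral_maf_range
    maf = rng_anc.uniform(lo, hi, size=m)
    flip = rng_anc.random(m) < 0.5
    ancestral = np.where(flip, maf, 1.0 - maf)

    chroms = np.repeat(
        [str(c + 1) for c in range(config.n_chromosomes)], config.markers_per_chromosome
    )
    positions = np.concatenate(
        [
            _sample_positions(rng_map, config.markers_per_chromosome, config.chromosome_length_bp)
            for _ in range(config.n_chromosomes)
        ]
    )
    allele_idx = rng_map.integers(0, 4, size=m)
    allele_alt = (allele_idx + 1 + rng_map.integers(0, 3, size=m)) % 4
    frame = pd.DataFrame(
        {
            "marker_id": [f"snp_{c}_{p}" for c, p in zip(chroms, positions)],
            "chromosome": chroms,
            "position_bp": positions,
            "allele1": _NUCLEOTIDES[allele_idx],
            "allele2": _NUCLEOTIDES[allele_alt],
        }
    )
    mm = MarkerMap(frame)

    f = config.per_population_f()
    k = config.n_populations
    pop_freqs = np.empty((k, m))
    for i in range(k):
        if f[i] == 0.0:
            pop_freqs[i] = ancestral  # degenerate Beta: no drift
        else:
            ratio = (1.0 - f[i]) / f[i]
            pop_freqs[i] = rng_pop.beta(ancestral * ratio, (1.0 - ancestral) * ratio)

    labels = config.labels()
    blocks = []
    sample_ids: list[str] = []
    populations: list[str] = []
    for i, n_i in enumerate(config.n_per_population):
        blocks.append(rng_geno.binomial(2, pop_freqs[i], size=(n_i, m)).astype(np.int8))
        sample_ids += [f"{labels[i]}_{j + 1:03d}" for j in range(n_i)]
        populations += [labels[i]] * n_i
    gm = GenotypeMatrix(np.vstack(blocks), sample_ids, populations)

    if config.missing_rate > 0 or config.het_error_rate > 0:
        gm = apply_noise(
            gm,
            missing_rate=config.missing_rate,
            het_error_rate=config.het_error_rate,
            rng=rng_noise,
        )

    truth = SimTruth(
        per_population_f=f,
        ancestral_freqs=ancestral,
        population_freqs=pop_freqs,
        population_labels=labels,
    )
    return gm, mm, truth


def plant_autozygous_segments(
    gm: GenotypeMatrix,
    mm: MarkerMap,
    segment_spec: Mapping[str, Sequence[tuple[str, int, int]]],
    seed: int,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Overwrite genomic intervals with autozygous (homozygous) genotypes.

    ``segment_spec`` maps sample_id -> list of ``(chromosome, start_bp,
    length_bp)``. Within each tract every marker is set to a non-missing
    homozygote by drawing a single allele from the empirical frequency of the
    sample's population and duplicating it, so tract allele content mirrors
    the local gene pool rather than being monomorphic. Overlapping tracts for
    one individual are a specification error; tracts spanning zero markers
    are recorded as empty and leave the genotypes untouched.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    calls = gm.calls.copy()
    sample_index = {s: i for i, s in enumerate(gm.sample_ids)}
    blocks = dict(mm.chromosome_blocks())
    positions = mm.positions

    pop_freq = {
        pop: allele_frequencies(gm, gm.population_mask(pop))
        for pop in gm.unique_populations()
    }

    planted: list[PlantedSegment] = []
    for sample_id in segment_spec:
        if sample_id not in sample_index:
            raise KeyError(f"unknown sample_id {sample_id!r}")
        segs = sorted(segment_spec[sample_id], key=lambda t: (t[0], t[1]))
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, length in segs:
            if length <= 0:
                raise ValueError("segment length must be positive")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(start) + int(length) - 1))
        for chrom, ivals in by_chrom.items():
            for (s0, e0), (s1, _e1) in zip(ivals, ivals[1:]):
                if s1 <= e0:
                    raise ValueError(
                        f"overlapping planted segments for {sample_id!r} on chromosome {chrom}"
                    )
        i = sample_index[sample_id]
        freq = pop_freq[gm.populations[i]]
        for chrom, start, length in segs:
            chrom = str(chrom)
            if chrom not in blocks:
                raise ValueError(f"chromosome {chrom!r} not in marker map")
            sl = blocks[chrom]
            end = int(start) + int(length) - 1
            lo = sl.start + int(np.searchsorted(positions[sl], start, side="left"))
            hi = sl.start + int(np.searchsorted(positions[sl], end, side="right"))
            if hi <= lo:
                planted.append(
                    PlantedSegment(sample_id, chrom, int(start), end, -1, -1, 0)
                )
                continue
            p = np.nan_to_num(freq[lo:hi], nan=0.5)
            allele2 = rng.random(hi - lo) < p
            calls[i, lo:hi] = np.where(allele2, 2, 0).astype(np.int8)
            planted.append(
                PlantedSegment(sample_id, chrom, int(start), end, lo, hi - 1, hi - lo)
            )

    truth = SimTruth(
        per_population_f=np.zeros(0),
        ancestral_freqs=np.zeros(0),
        population_freqs=np.zeros((0, 0)),
        population_labels=gm.unique_populations(),
        planted_segments=planted,
    )
    return GenotypeMatrix(calls, list(gm.sample_ids), list(gm.populations)), truth


def random_segment_spec(
    mm: MarkerMap,
    sample_ids: Sequence[str],
    n_segments: int,
    length_range_bp: tuple[int, int],
    seed: int,
    min_markers: int = 1,
) -> dict[str, list[tuple[str, int, int]]]:
    """Draw a random, per-individual non-overlapping planting specification.

    Tracts are placed uniformly on random chromosomes of random individuals;
    draws that would overlap an existing tract of the same individual or
    span fewer than ``min_markers`` markers are rejected and redrawn.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    blocks = mm.chromosome_blocks()
    positions = mm.positions
    chrom_span = {
        c: (int(positions[sl][0]), int(positions[sl][-1]), sl) for c, sl in blocks
    }
    chrom_names = [c for c, _ in blocks]
    spec: dict[str, list[tuple[str, int, int]]] = {}
    placed: dict[tuple[str, str], list[tuple[int, int]]] = {}
    attempts = 0
    count = 0
    while count < n_segments:
        attempts += 1
        if attempts > 200 * n_segments:
            raise RuntimeError("could not place requested segments without overlap")
        sample = str(sample_ids[rng.integers(len(sample_ids))])
        chrom = chrom_names[rng.integers(len(chrom_names))]
        first, last, sl = chrom_span[chrom]
        length = int(rng.integers(length_range_bp[0], length_range_bp[1] + 1))
        if last - first + 1 < length:
            continue
        start = int(rng.integers(first, last - length + 2))
        end = start + length - 1
        lo = int(np.searchsorted(positions[sl], start, side="left"))
        hi = int(np.searchsorted(positions[sl], end, side="right"))
        if hi - lo < min_markers:
            continue
        key = (sample, chrom)
        if any(not (end < s or e < start) for s, e in placed.get(key, [])):
            continue
        placed.setdefault(key, []).append((start, end))
        spec.setdefault(sample, []).append((chrom, start, length))
        count += 1
    return spec


def apply_noise(
    gm: GenotypeMatrix,
    missing_rate: float = 0.0,
    het_error_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Independently flip homozygotes to heterozygotes (``het_error_rate``)
    and then blank calls to missing (``missing_rate``)."""
    if not (0 <= missing_rate <= 1):
        raise ValueError("missing_rate must be in [0, 1]")
    if not (0 <= het_error_rate <= 1):
        raise ValueError("het_error_rate must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    calls = gm.calls.copy()
    if het_error_rate > 0:
        hom = (calls == 0) | (calls == 2)
        flip = hom & (rng.random(calls.shape) < het_error_rate)
        calls[flip] = 1
    if missing_rate > 0:
        blank = rng.random(calls.shape) < missing_rate
        calls[blank] = MISSING
    return GenotypeMatrix(calls, list(gm.sample_ids), list(gm.populations))
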