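"""Population differentiation, diversity and relatedness.

Implements per-breed expected/observed heterozygosity, pairwise and
per-marker F_ST (three estimators), a genotype PCA, method-of-moments IBD
sharing with duplicate / first-degree flags, and a VanRaden genomic
relationship matrix.

F_ST estimators
---------------
``wright``
    Per marker ``(H_T - H̄_S) / H_T`` with ``H_T = 2 p̄ (1 - p̄)`` from the
    pooled (allele-count weighted) frequency and ``H̄_S`` the unweighted mean
    of the two subpopulation heterozygosities; overall value is the ratio of
    sums over markers. Always in [0, 1] per marker; this is the statistic
    used for the outlier scan.
``weir_cockerham``
    The 1984 variance-components estimator (a / (a+b+c), ratio of sums);
    nearly unbiased for the divergence parameter of an island model, may be
    slightly negative per marker (never clamped).
``hudson``
    ``1 - Hw/Hb`` with unbiased within-population heterozygosity; also
    estimates the generating divergence directly and is the estimator the
    simulator's Monte-Carlo checks use.

The 95% CI on the overall value is a seeded bootstrap over markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, MISSING

ESTIMATORS = ("wright", "weir_cockerham", "hudson")


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def heterozygosity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Expected (2p(1-p), from within-population frequencies) and observed
    (het-call fraction) heterozygosity averaged over markers, per population."""
    rows = []
    for pop in gm.unique_populations():
        calls = gm.calls[gm.population_mask(pop)]
        valid = calls >= 0
        n_alleles = 2 * valid.sum(axis=0)
        informative = n_alleles > 0
        alt = np.where(valid, calls, 0).sum(axis=0)
        p = alt[informative] / n_alleles[informative]
        he = float(np.mean(2 * p * (1 - p)))
        with np.errstate(invalid="ignore"):
            ho_marker = (calls == 1).sum(axis=0)[informative] / valid.sum(axis=0)[informative]
        rows.append({"population": pop, "He": he, "Ho": float(np.mean(ho_marker))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    population_pair: tuple[str, str]
    estimator: str
    fst_overall: float
    ci_low: float
    ci_high: float
    per_marker_fst: np.ndarray  # NaN where undefined
    n_markers_used: int


def _pair_counts(gm: GenotypeMatrix, pop_a: str, pop_b: str):
    stats = []
    for pop in (pop_a, pop_b):
        mask = gm.population_mask(pop)
        if not mask.any():
            raise ValueError(f"population {pop!r} not present")
        calls = gm.calls[mask]
        valid = calls >= 0
        n = valid.sum(axis=0).astype(float)  # diploid counts
        alt = np.where(valid, calls, 0).sum(axis=0).astype(float)
        het = (calls == 1).sum(axis=0).astype(float)
        stats.append((n, alt, het))
    return stats


def _fst_components(
    gm: GenotypeMatrix, pop_a: str, pop_b: str, estimator: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (numerator, denominator, usable) arrays; overall F_ST is
    sum(num)/sum(den) over usable markers."""
    (n1, a1, h1), (n2, a2, h2) = _pair_counts(gm, pop_a, pop_b)
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = a1 / (2 * n1)
        p2 = a2 / (2 * n2)

    if estimator == "wright":
        pbar = (a1 + a2) / (2 * (n1 + n2))
        ht = 2 * pbar * (1 - pbar)
        # subpopulation heterozygosity weighted by called sample counts, the
        # same weighting as pbar, which keeps H_T - H_S = 2 Var_w(p) >= 0
        w1, w2 = n1 / (n1 + n2), n2 / (n1 + n2)
        hs = w1 * 2 * p1 * (1 - p1) + w2 * 2 * p2 * (1 - p2)
        num, den = ht - hs, ht
        usable = usable & (den > 0)
    elif estimator == "hudson":
        hw = (
            (2 * n1 / (2 * n1 - 1)) * 2 * p1 * (1 - p1)
            + (2 * n2 / (2 * n2 - 1)) * 2 * p2 * (1 - p2)
        ) / 2
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        num, den = hb - hw, hb
        usable = usable & (den > 0)
    elif estimator == "weir_cockerham":
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (h1 + h2) / (n1 + n2)
        pq = pbar * (1 - pbar)
        inner = pq - (r - 1) / r * s2 - hbar / 4
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num, den = a, a + b + c
        usable = usable & (den != 0) & np.isfinite(den)
        # markers monomorphic in the pooled pair carry no information
        usable = usable & ~((pbar == 0) | (pbar == 1))
    else:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")

    num = np.where(usable, num, 0.0)
    den = np.where(usable, den, 0.0)
    return num, den, usable


def pairwise_fst(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    estimator: str = "wright",
    n_boot: int = 1000,
    seed: int | None = None,
) -> FstResult:
    """Overall (ratio of sums) and per-marker F_ST between two populations,
    with a marker-bootstrap 95% CI (``n_boot=0`` skips the bootstrap)."""
    num, den, usable = _fst_components(gm, pop_a, pop_b, estimator)
    if not usable.any():
        raise ValueError("no usable markers for this pair")
    overall = float(num.sum() / den.sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        per_marker = np.where(usable, num / np.where(usable, den, 1.0), np.nan)

    ci_low = ci_high = float("nan")
    if n_boot:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        m = len(num)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, m, size=m)
            s = den[idx].sum()
            reps[b] = num[idx].sum() / s if s else np.nan
        ci_low, ci_high = (float(q) for q in np.nanpercentile(reps, [2.5, 97.5]))

    return FstResult(
        population_pair=(pop_a, pop_b),
        estimator=estimator,
        fst_overall=overall,
        ci_low=ci_low,
        ci_high=ci_high,
        per_marker_fst=per_marker,
        n_markers_used=int(usable.sum()),
    )


def fst_outlier_scan(result: FstResult, threshold: float = 0.5) -> np.ndarray:
    """Indices of markers whose per-marker F_ST strictly exceeds the
    threshold; undefined (NaN) markers are never outliers."""
    values = result.per_marker_fst
    with np.errstate(invalid="ignore"):
        return np.flatnonzero(np.nan_to_num(values, nan=-np.inf) > threshold)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # descending, >= 0
    scores: pd.DataFrame  # sample_id, population, PC1..PCk
    explained_variance_ratio: np.ndarray


def pca(gm: GenotypeMatrix, n_components: int = 10, standardize: bool = True) -> PcaResult:
    """Genotype PCA: missing calls mean-imputed (2p̂), columns centred by
    2p̂ and, when ``standardize``, scaled by sqrt(2p̂(1-p̂)); zero-variance
    markers are dropped with a warning. Run on an LD-pruned marker set for
    structure inference."""
    from sklearn.decomposition import PCA as SkPCA

    calls = gm.calls.astype(float)
    calls[calls == MISSING] = np.nan
    p = np.nanmean(calls, axis=0) / 2.0  # per-marker allele frequency
    var_ok = np.isfinite(p) & (p > 0) & (p < 1)
    if not var_ok.all():
        warnings.warn(
            f"dropping {int((~var_ok).sum())} zero-variance/uncalled marker(s) before PCA",
            stacklevel=2,
        )
    calls = calls[:, var_ok]
    p = p[var_ok]
    mu = 2 * p
    X = np.where(np.isnan(calls), mu, calls) - mu
    if standardize:
        X = X / np.sqrt(2 * p * (1 - p))

    k = min(n_components, min(X.shape) - 1 if min(X.shape) > 1 else 1)
    model = SkPCA(n_components=k, svd_solver="full", random_state=0)
    scores = model.fit_transform(X)
    frame = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    frame.insert(0, "population", gm.populations)
    frame.insert(0, "sample_id", gm.sample_ids)
    return PcaResult(
        eigenvalues=model.explained_variance_.copy(),
        scores=frame,
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
    )


# ---------------------------------------------------------------------------
# IBD and GRM
# ---------------------------------------------------------------------------

@dataclass
class RelatednessResult:
    ibd: pd.DataFrame  # sample_a, sample_b, z0, z1, z2, pi_hat, flags
    grm: np.ndarray
    sample_ids: list[str]
    block_means: pd.DataFrame  # population pair -> mean GRM entry


def ibd_and_grm(
    gm: GenotypeMatrix,
    duplicate_threshold: float = 0.95,
    first_degree_threshold: float = 0.5,
) -> RelatednessResult:
    """Pairwise IBD sharing (method of moments over IBS counts) and a
    VanRaden genomic relationship matrix.

    Expected IBS counts under each IBD state use pooled sample allele
    frequencies and are scaled per pair by its shared non-missing marker
    fraction (missingness assumed marker-random). ``pi_hat = Z2 + Z1/2``,
    with the state probabilities clamped to [0, 1] and renormalized.
    Monomorphic markers are excluded. Run on an LD-pruned marker set.
    """
    calls = gm.calls
    valid = calls >= 0
    n_alleles = 2 * valid.sum(axis=0)
    alt = np.where(valid, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers")
    calls = calls[:, poly]
    valid = valid[:, poly]
    p = p[poly]
    q = 1 - p
    n, m = calls.shape

    h0 = ((calls == 0) & valid).astype(np.float64)
    h1 = ((calls == 1) & valid).astype(np.float64)
    h2 = ((calls == 2) & valid).astype(np.float64)
    vf = valid.astype(np.float64)

    ibs2 = h0 @ h0.T + h1 @ h1.T + h2 @ h2.T
    ibs0 = h0 @ h2.T + h2 @ h0.T
    n_shared = vf @ vf.T
    ibs1 = n_shared - ibs2 - ibs0

    # expected per-marker IBS probabilities given IBD state, summed over markers
    e0_z0 = float(np.sum(2 * p**2 * q**2))
    e1_z0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_z0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_z1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_z1 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))

    scale = n_shared / m
    with np.errstate(divide="ignore", invalid="ignore"):
        z0 = ibs0 / (e0_z0 * scale)
        z1 = (ibs1 - z0 * e1_z0 * scale) / (e1_z1 * scale)
        z2 = (ibs2 - z0 * e2_z0 * scale - z1 * e2_z1 * scale) / n_shared
    z = np.clip(np.stack([z0, z1, z2]), 0.0, 1.0)
    total = z.sum(axis=0, keepdims=True)
    z = np.where(total > 0, z / np.where(total > 0, total, 1.0), np.array([1.0, 0.0, 0.0])[:, None, None])
    pi_hat = np.clip(z[2] + z[1] / 2, 0.0, 1.0)

    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append(
                (
                    gm.sample_ids[i],
                    gm.sample_ids[j],
                    gm.populations[i],
                    gm.populations[j],
                    z[0, i, j],
                    z[1, i, j],
                    z[2, i, j],
                    pi_hat[i, j],
                )
            )
    ibd = pd.DataFrame(
        rows,
        columns=["sample_a", "sample_b", "pop_a", "pop_b", "z0", "z1", "z2", "pi_hat"],
    )
    ibd["duplicate"] = ibd["pi_hat"] > duplicate_threshold
    ibd["first_degree"] = ibd["pi_hat"] > first_degree_threshold

    # VanRaden method 1 GRM (missing imputed at 2p)
    X = calls.astype(float)
    X[~valid] = np.nan
    Z = np.where(np.isnan(X), 0.0, X - 2 * p)
    grm = (Z @ Z.T) / (2 * np.sum(p * q))

    pops = gm.unique_populations()
    block_rows = []
    pop_arr = np.asarray(gm.populations)
    for a_i, pa in enumerate(pops):
        for pb in pops[a_i:]:
            ma = pop_arr == pa
            mb = pop_arr == pb
            block = grm[np.ix_(ma, mb)]
            if pa == pb:
                iu = np.triu_indices(block.shape[0], k=1)
                val = float(block[iu].mean()) if len(iu[0]) else float("nan")
            else:
                val = float(block.mean())
            block_rows.append({"pop_a": pa, "pop_b": pb, "mean_grm": val})
    return RelatednessResult(
        ibd=ibd,
        grm=grm,
        sample_ids=list(gm.sample_ids),
        block_means=pd.DataFrame(block_rows),
    )
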