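# Methods

This note documents the models, rules and numerical conventions the package
implements, the design choices made where the field's conventions leave the
design open, and what the synthetic-data validation does and does not show.

## ROH definition and scanning

A run of homozygosity is scored per individual within one chromosome over
position-sorted markers. The rule set has five parameters
(`RohParams`): minimum span 1,000,000 bp, minimum 60 SNPs, zero
heterozygous and zero missing calls inside the run, and a maximum
inter-SNP gap of 1,000,000 bp. A run extends while the current call is a
non-missing homozygote and its distance to the previous marker is within
the gap; any violation closes the run, and a gap-breaking marker may start
a new one. The scanner is equivalent to enumerating all maximal windows
satisfying the constraints and keeping those above both floors — the test
suite asserts set equality against an independent enumerator on a thousand
randomized instances.

Conventions fixed here because they are ambiguous at the source:

* **Length** is `end_bp − start_bp + 1` with 1-based inclusive positions of
  the first and last SNP of the run. The ±1 is irrelevant at Mb scale but is
  fixed for exactness.
* **Length classes** <2 / 2–4 / 4–8 / 8–16 / >16 Mb are left-closed,
  right-open; a segment of exactly 4,000,000 bp falls in 4–8 Mb.
* **The SNP-count and length floors are ANDed** — both must hold.
* `max_het`/`max_missing` exist as parameters but only the strict value 0 is
  implemented; the relaxed semantics (which maximal window "uses" an allowed
  heterozygote?) is not well defined for a rule-based scanner, and the
  target analyses allow none.
* The scanner refuses an unsorted marker map instead of silently
  re-sorting: silent reordering would desynchronize the genotype columns.

No LD pruning precedes ROH detection; the 1 Mb / 60-SNP floor is the
guard against short LD-induced runs.

A property worth knowing: tightening `min_snps` or `min_length_bp` can only
remove segments, but widening `max_gap_bp` is **not** monotone in the
segment count — it can merge two qualifying runs into one. The quantity
that is monotone under a wider gap allowance is the set of markers covered
by reported segments, and that is what the property test asserts.

## Inbreeding coefficients

**F_ROH = L_ROH / L_AUT.** `L_AUT` defaults to 2,487,082,459 bp, the
autosomal length covered by the 150K bovine chip; for simulated genomes the
pipeline substitutes the map's own covered length
(Σ per chromosome of last − first position + 1), since the denominator is
defined by chip coverage and differs per dataset. All segment lengths are
accumulated as exact integers; every reported ratio is a single correctly
rounded division. Consequently the chromosome and length-class partitions
of F_ROH are exactly additive as rational numbers (the integer ledgers are
exposed as `by_chromosome_bp` / `by_class_bp`), while the float ratios
agree with the total to within ~1 ulp.

**Excess homozygosity.** F = (O − E)/(L − E) per individual with
E = Σ over the individual's non-missing markers of (1 − 2 p q). By default
p is the pooled-cohort frequency; per-breed frequencies can be passed when
measuring departure within a breed. Monomorphic markers contribute 1 to E;
an individual typed only at monomorphic markers has L = E and is reported
as F = 0 with a `degenerate` flag rather than a division error.

**Regression.** F (response) on F_ROH (predictor), ordinary least squares
per population, requiring ≥ 3 individuals. Zero variance in F_ROH is
flagged with NaN coefficients; a constant response gives slope 0, R² 0.

## QC and LD pruning

QC order is fixed: (1) drop markers without a positive position or outside
the autosome set ("1"–"29" for cattle; non-autosomal labels are accepted at
load and flagged here); (2) drop samples with call rate ≤ the threshold;
(3) drop markers with call rate ≤ the threshold, computed on the retained
samples. Call rate is the non-missing fraction, and the thresholds are
exclusive (keep strictly above 0.90). The filter is idempotent on its own
output in practice; this is not a theorem — deleting markers can in
principle lift a borderline sample across the threshold on a second pass —
and the test asserts it on generated data.

LD pruning removes markers so that no retained pair within a 50-marker
window has squared Pearson correlation of genotype codes above 0.5, with r²
computed over pairwise-complete samples. Windows advance 5 markers at a
time over the *currently retained* markers of a chromosome and the pass
repeats until stable, which makes the output self-verifying (an audit
helper counts violations; it must find zero). Of an offending pair the
lower-MAF member is removed, ties going against the later marker. The
window/step/removal conventions follow the dominant community practice;
the exact traversal of the original GUI implementations of this analysis is
undocumented, so pruned-marker counts from other software are not expected
to match marker-for-marker.

## Differentiation, PCA, relatedness

Three F_ST estimators are implemented, all reported per marker and overall
as a ratio of sums over markers:

* **wright** (default, and the outlier-scan statistic):
  (H_T − H_S)/H_T with H_T = 2 p̄ q̄ from the pooled frequency and H_S the
  call-count-weighted mean subpopulation heterozygosity. The weighting
  matches the pooled frequency's, which makes H_T − H_S = 2·Var_w(p) ≥ 0 and
  keeps every per-marker value in [0, 1] even with unequal per-marker sample
  sizes from missing calls.
* **weir_cockerham**: the 1984 variance-components a/(a+b+c); per-marker
  values may be slightly negative and are never clamped.
* **hudson**: 1 − H_w/H_b with unbiased within-population heterozygosity.

Under a Balding–Nichols draw at per-population divergence F, the wright
form estimates F/(2−F) — the classical two-deme variance decomposition —
while hudson and weir_cockerham estimate F itself; the simulator's
parameter-recovery checks therefore use the latter two. The bootstrap CI
resamples markers with a seeded generator (default 1,000 replicates).
Markers monomorphic across both populations are undefined, excluded from
the ratio of sums, reported as NaN and never flagged by the outlier scan
(threshold strictly >, default 0.5, run on the full QC'd marker set — the
marker-level scan is not pruned).

PCA mean-imputes missing calls at 2p̂, centres by 2p̂ and (by default)
scales by √(2p̂q̂), dropping zero-variance markers with a warning; an
LD-pruned input is recommended for structure inference. IBD uses the
method-of-moments decomposition of IBS counts into (Z0, Z1, Z2) with
expectations from pooled sample allele frequencies, scaled per pair by its
shared non-missing fraction (missingness treated as marker-random); the
small-sample correction factors some implementations apply are omitted,
which at the cohort sizes targeted here shifts π̂ by far less than the
0.95/0.5 flag margins. States are clamped to [0, 1] and renormalized. The
GRM is VanRaden method 1 on 2p̂-imputed genotypes; on Hardy–Weinberg
simulations its mean diagonal is ≈ 1 + mean inbreeding.

## ROH islands and annotation

Occurrence = number of individuals of one population whose ROH cover a
marker (each individual at most once; per-individual segments are
non-overlapping by construction). The TOP-SNP threshold is the occurrence
at rank ⌈fraction·M⌉ (default 1%) of the descending profile; all markers at
or above it qualify, so ties can push the set beyond the nominal 1% —
deliberate, because occurrence is integer-valued and thresholds are
naturally tied. An all-zero profile yields an empty set with a warning, and
a threshold that lands at zero occurrence (a profile almost everywhere
zero) warns that the whole map qualifies.

TOP SNPs are merged into islands while consecutive TOP SNPs of a chromosome
are ≤ 1 Mb apart (the merge gap mirrors the ROH gap rule and is
configurable); island bounds are the first/last TOP SNP positions — not
extended to flanking non-TOP markers. Annotation is plain interval
intersection (≥ 1 bp, half-open arithmetic internally, 1-based inclusive
coordinates on output) against BED or GFF3 tracks; gene classification is
positional only, with no transcript-consequence prediction. Cross-population
sharing intersects island intervals over every subset of populations and
partitions the per-population gene sets Venn-style; the partition sizes sum
to the union by construction.

## The synthetic generator

The generator emulates the statistical structure this analysis assumes and
nothing more. Divergence follows Balding–Nichols: ancestral MAF uniform on
(0.05, 0.5] (orientation randomized), population frequency
Beta(p(1−F)/F, (1−p)(1−F)/F) — degenerate at F = 0, where the ancestral
frequency is used directly — and genotypes binomial(2, p_k), i.e.
within-population Hardy–Weinberg with free recombination between markers.
A pairwise F_ST target matrix M is converted to per-population divergences
through M[k,l] = (F_k + F_l)/2, the Hudson expectation of a pairwise
comparison under this model; the default targets (0.019 / 0.052 / 0.050)
place three populations in the regime of closely related breeds and solve
to per-population F = (0.021, 0.017, 0.083).

Defaults are a desk-scale profile: 3 populations × 50 individuals,
29 chromosomes × 700 markers (~20K markers) on 13.3 Mb chromosomes, i.e.
~19 kb marker spacing — the density of a 150K bovine chip — with
missingness 0.002 and no genotyping error. Marker positions are uniform
draws (deduplicated, sorted); one integer seed feeds a
`numpy.random.SeedSequence` whose children are consumed in a fixed order,
so a given seed yields bit-identical datasets.

Autozygous tracts are planted by overwriting each marker in the tract with
a homozygote whose allele is a fresh draw from the empirical frequency of
the individual's population — tracts therefore have realistic allele
content instead of being monomorphic. The ground truth records requested
bounds and the exact first/last marker covered. Validation scales: the
planted-recovery and divergence-recovery tests run at 20K markers with the
population sizes stated in their docstrings (150–400 individuals), sizes at
which every check completes in seconds while the Monte-Carlo error stays
well inside the asserted tolerances.

**Recovery metric.** A planted tract is fully homozygous, so the rule-based
caller always covers it; by chance the flanking background is homozygous
too (each flanking marker with probability 1 − 2pq ≈ 0.55–0.9), so the
maximal run frequently extends a few markers beyond the planted boundary.
Such extension is *correct* behaviour for a rule-based definition — it is
indistinguishable from autozygosity at the marker level, and the oracle
equivalence test demands it. Recovery is therefore scored as the planted
markers a call fails to cover (required: at most one marker interval),
never as outward extension; false positives are calls that overlap no
planted tract at all, which the noise-free background effectively never
produces (a chance 60-homozygote run has probability ~e⁻²⁰ per locus).

**What passing does not show.** The generator has no LD beyond the planted
tracts, no recombination map, no ascertainment bias, no pedigree structure
and no genotype-calling artefacts correlated along the chip. Tests passing
on it validate the *implementations* (the scanner against its definition,
the estimators against their generating parameters), not the biological
calibration of thresholds on real chip data; published cohort-specific
results (mean ROH counts, island coordinates, pruned-marker counts,
eigenvalue scales) depend on unreleased genotypes and are out of reach by
design.

## Degenerate inputs and tie-breaks, collected

* Duplicate marker ids, non-increasing positions within a chromosome →
  load-time errors; position 0 / non-autosomes are legal at load and
  removed by QC with named reasons.
* PED/MAP text round trips recover allele orientation only when the first
  called genotype at a marker contains allele1 (MAP has no allele columns);
  binary and VCF round trips are exact, including missing calls.
* r² with fewer than two pairwise-complete samples, or zero variance, is
  treated as 0 (no pruning action).
* Bootstrap replicates with a zero denominator (all-monomorphic resample)
  are NaN and ignored by the percentile.
* Empty-after-QC, empty marker sets, unknown populations and unknown
  configuration keys all raise named errors rather than producing empty
  outputs; a failing pipeline stage aborts with the stage name.
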