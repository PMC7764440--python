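"""Simulate three diverged cattle-like populations and call runs of
homozygosity with the standard medium-density chip rule set (>= 1 Mb,
>= 60 consecutive homozygous SNPs, no het/missing, gap <= 1 Mb).

Background genotypes are Hardy-Weinberg draws, so without planted
autozygosity essentially no run survives the 60-SNP floor; the planted
10-individual tracts are what the caller reports.
"""

from rohscan import (
    SimConfig,
    detect_roh,
    plant_autozygous_segments,
    random_segment_spec,
    simulate_populations,
    summarize_roh,
)

cfg = SimConfig(seed=1)  # 3 populations x 50, 29 chromosomes x 700 markers
gm, mm, truth = simulate_populations(cfg)
print(f"simulated {gm.n_samples} individuals x {mm.n_markers} markers")
print("per-population divergence from the ancestral pool:", truth.per_population_f.round(3))

spec = random_segment_spec(
    mm, gm.sample_ids[:10], n_segments=25, length_range_bp=(1_500_000, 8_000_000),
    seed=2, min_markers=60,
)
gm, planted = plant_autozygous_segments(gm, mm, spec, seed=3)
print(f"planted {len(planted.planted_segments)} autozygous tracts into 10 individuals")

segments = detect_roh(gm, mm)
summary = summarize_roh(segments, gm.population_of())
print(f"\ndetected {len(segments)} ROH")
print(summary.population_stats.to_string(index=False))
print("\nEach row: total ROH in that population, the min/max/mean count per")
print("individual, and the min/max/mean segment length in bp.")
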