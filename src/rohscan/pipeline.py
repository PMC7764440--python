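"""End-to-end orchestration from a single YAML/dict configuration.

Stages: load or simulate genotypes -> QC -> LD pruning -> ROH detection and
summaries -> inbreeding (F_ROH + excess-homozygosity F + regression) ->
structure (He/Ho, pairwise F_ST with outlier scan, PCA, IBD/GRM) -> ROH
islands per population (+ optional gene/QTL annotation). Every stage writes
plain TSV/JSON files into the output directory, plus a manifest recording
the package version, parameters, seed and input checksums; reruns with the
same configuration and inputs are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inbreeding import (
    excess_homozygosity_f,
    f_vs_froh_regression,
    population_inbreeding_summary,
    roh_inbreeding,
)
from .io import read_plink_binary, read_plink_text, read_vcf
from .islands import (
    build_islands,
    intersect_annotation,
    islands_to_frame,
    occurrence_profile,
    qtl_class_counts,
    read_bed_features,
    read_gff3_features,
    top_snp_threshold,
)
from .qc import qc_filter, ld_prune
from .roh import RohParams, chromosome_coverage, detect_roh, segments_to_bed, summarize_roh
from .simulate import SimConfig, simulate_populations
from .structure import fst_outlier_scan, heterozygosity, ibd_and_grm, pairwise_fst, pca
from .types import L_AUT_BP, covered_autosome_length, segments_to_frame


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown configuration key(s) in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated pipeline configuration; stage defaults are the standard
    medium-density chip parameters."""

    output_dir: str
    seed: int = 0
    # input: exactly one of plink_prefix / ped+map / vcf / simulate
    plink_prefix: str | None = None
    ped: str | None = None
    map: str | None = None
    vcf: str | None = None
    simulate: dict | None = None
    populations_file: str | None = None  # TSV sample_id<TAB>population for VCF input
    l_aut_bp: float | None = None  # default: chip constant for real data, map coverage for simulated
    qc: dict = field(default_factory=dict)
    prune: dict = field(default_factory=dict)
    roh: dict = field(default_factory=dict)
    fst: dict = field(default_factory=dict)
    islands: dict = field(default_factory=dict)
    annotation: dict = field(default_factory=dict)

    _QC_KEYS = {"sample_cr_min", "marker_cr_min"}
    _PRUNE_KEYS = {"window_snps", "step_snps", "r2_max", "enabled"}
    _ROH_KEYS = {"min_length_bp", "min_snps", "max_gap_bp", "max_het", "max_missing"}
    _FST_KEYS = {"estimator", "n_boot", "outlier_threshold"}
    _ISLAND_KEYS = {"top_fraction", "merge_gap_bp"}
    _ANNOT_KEYS = {"genes_bed", "genes_gff3", "qtl_bed", "qtl_class_column"}

    def __post_init__(self) -> None:
        sources = [
            self.plink_prefix is not None,
            self.ped is not None or self.map is not None,
            self.vcf is not None,
            self.simulate is not None,
        ]
        if sum(sources) != 1:
            raise ValueError("configure exactly one input source")
        if (self.ped is None) != (self.map is None):
            raise ValueError("ped and map must be given together")
        _check_keys(self.qc, self._QC_KEYS, "qc")
        _check_keys(self.prune, self._PRUNE_KEYS, "prune")
        _check_keys(self.roh, self._ROH_KEYS, "roh")
        _check_keys(self.fst, self._FST_KEYS, "fst")
        _check_keys(self.islands, self._ISLAND_KEYS, "islands")
        _check_keys(self.annotation, self._ANNOT_KEYS, "annotation")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        _check_keys(data, {f.name for f in fields(cls) if not f.name.startswith("_")}, "run config")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "rohscan_version": __version__,
        "seed": config.seed,
        "parameters": {
            "qc": config.qc,
            "prune": config.prune,
            "roh": config.roh,
            "fst": config.fst,
            "islands": config.islands,
        },
        "inputs": {},
        "outputs": [],
    }

    def record(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(out)))

    stage = "load"
    try:
        simulated = config.simulate is not None
        if simulated:
            sim_cfg = SimConfig(**{"seed": config.seed, **config.simulate})
            gm, mm, _truth = simulate_populations(sim_cfg)
            manifest["inputs"]["simulate"] = {
                k: v for k, v in asdict(sim_cfg).items() if not isinstance(v, np.ndarray)
            }
        elif config.plink_prefix is not None:
            p = Path(config.plink_prefix)
            paths = [p.with_suffix(s) for s in (".bed", ".bim", ".fam")]
            gm, mm = read_plink_binary(*paths)
            manifest["inputs"].update({q.name: _sha256(q) for q in paths})
        elif config.ped is not None:
            gm, mm = read_plink_text(config.ped, config.map)
            manifest["inputs"].update(
                {Path(q).name: _sha256(Path(q)) for q in (config.ped, config.map)}
            )
        else:
            pops = None
            if config.populations_file:
                tbl = pd.read_csv(config.populations_file, sep="\t", header=None, dtype=str)
                pops = dict(zip(tbl[0], tbl[1]))
            gm, mm = read_vcf(config.vcf, populations=pops)
            manifest["inputs"][Path(config.vcf).name] = _sha256(Path(config.vcf))

        stage = "qc"
        gm, mm, qc_report = qc_filter(gm, mm, **config.qc)
        _write_tsv(qc_report.to_frame(), out / "qc_report.tsv")
        _write_tsv(qc_report.removed_samples, out / "qc_removed_samples.tsv")
        _write_tsv(qc_report.removed_markers, out / "qc_removed_markers.tsv")
        record(out / "qc_report.tsv")
        record(out / "qc_removed_samples.tsv")
        record(out / "qc_removed_markers.tsv")

        stage = "prune"
        prune_cfg = dict(config.prune)
        prune_enabled = prune_cfg.pop("enabled", True)
        if prune_enabled:
            kept = ld_prune(gm, mm, **prune_cfg)
        else:
            kept = np.arange(gm.n_markers)
        (out / "pruned_keep.txt").write_text(
            "\n".join(mm.marker_ids[kept]) + "\n"
        )
        record(out / "pruned_keep.txt")
        gm_pruned = gm.subset_markers(kept)
        mm_pruned = mm.subset(kept)

        stage = "roh"
        params = RohParams(**config.roh)
        segments = detect_roh(gm, mm, params)  # never on pruned markers
        seg_frame = segments_to_frame(segments)
        _write_tsv(seg_frame, out / "roh_segments.tsv")
        _write_tsv(segments_to_bed(segments), out / "roh_segments.bed")
        record(out / "roh_segments.tsv")
        record(out / "roh_segments.bed")
        pop_of = gm.population_of()
        summary = summarize_roh(segments, pop_of)
        _write_tsv(summary.population_stats, out / "roh_population_stats.tsv")
        _write_tsv(summary.individual_stats, out / "roh_individual_stats.tsv")
        _write_tsv(summary.class_stats, out / "roh_class_stats.tsv")
        _write_tsv(chromosome_coverage(segments, mm), out / "roh_chromosomes.tsv")
        for name in (
            "roh_population_stats.tsv",
            "roh_individual_stats.tsv",
            "roh_class_stats.tsv",
            "roh_chromosomes.tsv",
        ):
            record(out / name)

        stage = "inbreeding"
        l_aut = config.l_aut_bp or (covered_autosome_length(mm) if simulated else L_AUT_BP)
        roh_inb = roh_inbreeding(segments, pop_of, l_aut_bp=l_aut)
        f_table = excess_homozygosity_f(gm)
        _write_tsv(roh_inb.table, out / "inbreeding_froh.tsv")
        _write_tsv(f_table, out / "inbreeding_f.tsv")
        _write_tsv(
            population_inbreeding_summary(f_table, roh_inb.table),
            out / "inbreeding_summary.tsv",
        )
        merged = f_table.merge(roh_inb.table[["sample_id", "f_roh"]], on="sample_id")
        _write_tsv(
            f_vs_froh_regression(merged["f"], merged["f_roh"], merged["population"]),
            out / "inbreeding_regression.tsv",
        )
        for name in (
            "inbreeding_froh.tsv",
            "inbreeding_f.tsv",
            "inbreeding_summary.tsv",
            "inbreeding_regression.tsv",
        ):
            record(out / name)
        manifest["parameters"]["l_aut_bp"] = l_aut

        stage = "structure"
        _write_tsv(heterozygosity(gm), out / "heterozygosity.tsv")
        record(out / "heterozygosity.tsv")
        pops = gm.unique_populations()
        fst_cfg = dict(config.fst)
        threshold = fst_cfg.pop("outlier_threshold", 0.5)
        fst_rows, outlier_rows = [], []
        for i, pa in enumerate(pops):
            for pb in pops[i + 1 :]:
                res = pairwise_fst(gm_pruned, pa, pb, seed=config.seed, **fst_cfg)
                fst_rows.append(
                    {
                        "pop_a": pa,
                        "pop_b": pb,
                        "estimator": res.estimator,
                        "fst": res.fst_overall,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                    }
                )
                # the marker-level scan runs on the full QC'd set, unpruned
                scan = pairwise_fst(gm, pa, pb, n_boot=0, estimator=res.estimator)
                for idx in fst_outlier_scan(scan, threshold):
                    outlier_rows.append(
                        {
                            "pop_a": pa,
                            "pop_b": pb,
                            "marker_id": mm.marker_ids[idx],
                            "chromosome": mm.chromosomes[idx],
                            "position_bp": int(mm.positions[idx]),
                            "fst": float(scan.per_marker_fst[idx]),
                        }
                    )
        if len(pops) > 1:
            _write_tsv(pd.DataFrame(fst_rows), out / "fst_pairwise.tsv")
            _write_tsv(
                pd.DataFrame(
                    outlier_rows,
                    columns=["pop_a", "pop_b", "marker_id", "chromosome", "position_bp", "fst"],
                ),
                out / "fst_outliers.tsv",
            )
            record(out / "fst_pairwise.tsv")
            record(out / "fst_outliers.tsv")

        pca_res = pca(gm_pruned)
        _write_tsv(pca_res.scores, out / "pca_scores.tsv")
        record(out / "pca_scores.tsv")
        rel = ibd_and_grm(gm_pruned)
        _write_tsv(rel.ibd, out / "ibd_pairs.tsv")
        _write_tsv(rel.block_means, out / "grm_block_means.tsv")
        record(out / "ibd_pairs.tsv")
        record(out / "grm_block_means.tsv")

        stage = "islands"
        isl_cfg = dict(config.islands)
        top_fraction = isl_cfg.pop("top_fraction", 0.01)
        merge_gap = isl_cfg.pop("merge_gap_bp", 1_000_000)
        genes = qtls = None
        ann = config.annotation
        if ann.get("genes_bed"):
            genes = read_bed_features(ann["genes_bed"])
        elif ann.get("genes_gff3"):
            genes = read_gff3_features(ann["genes_gff3"])
        if ann.get("qtl_bed"):
            qtls = read_bed_features(ann["qtl_bed"], feature_class_column=ann.get("qtl_class_column"))

        all_islands = []
        annotated_rows = []
        for pop in pops:
            ids = [s for s, p in pop_of.items() if p == pop]
            prof = occurrence_profile(segments, mm, ids, pop)
            _, top = top_snp_threshold(prof, top_fraction) if prof.counts.max() else (0, np.array([], int))
            isl = build_islands(top, prof, mm, merge_gap)
            all_islands += isl
            if genes is not None or qtls is not None:
                for a in intersect_annotation(isl, genes, qtls):
                    annotated_rows.append(
                        {
                            "population": pop,
                            "chromosome": a.island.chromosome,
                            "start_bp": a.island.start_bp,
                            "end_bp": a.island.end_bp,
                            "genes": ",".join(a.genes),
                            "qtls": ",".join(n for n, _ in a.qtls),
                        }
                    )
        _write_tsv(islands_to_frame(all_islands), out / "roh_islands.tsv")
        record(out / "roh_islands.tsv")
        if annotated_rows:
            _write_tsv(pd.DataFrame(annotated_rows), out / "roh_islands_annotated.tsv")
            record(out / "roh_islands_annotated.tsv")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
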