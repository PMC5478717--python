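"""End-to-end orchestration on the synthetic community.

One call generates a labeled community, fragments it into contigs, simulates
the metagenome, bins contigs by composition and coverage, scores binning
against truth, recovers marker completeness per bin with extrapolated genome
sizes, recruits the reads against every genome (RPKG), computes the pairwise
ANI matrix and the intergenic-spacer statistics, and returns one
JSON-serializable report.  All randomness flows from the single top-level
seed through per-stage derived seeds (seed + stage index), so any stage can
be re-run in isolation and the whole report is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import composition_binning as cb
from . import genome_stats, marker_completeness, recruitment, synthetic_community as sc
from .io_formats import SeqRecord
from .marker_completeness import MarkerSet

# stage indices for derived seeds
_STAGE_GENOMES = 0
_STAGE_CONTIGS = 1
_STAGE_READS = 2
_STAGE_BINNING = 3
_STAGE_GENES = 4


@dataclass
class GenomeSpec:
    id: str
    length: int
    gc: float
    coverage: float
    n_markers: int  # implanted markers from the 35-gene universal set


@dataclass
class RunConfig:
    """Community composition and per-stage thresholds for one pipeline run.

    The default community holds three genomes separated in both GC and
    coverage, contigs of at least 5 kb, shotgun reads of 100 bp at 2%
    substitution error, and the standard recruitment filters (>= 50 bp,
    >= 95% identity).
    """

    seed: int = 0
    genomes: list[GenomeSpec] = field(
        default_factory=lambda: [
            GenomeSpec("gA", 100_000, 0.35, 5.0, 34),
            GenomeSpec("gB", 100_000, 0.50, 20.0, 35),
            GenomeSpec("gC", 100_000, 0.65, 80.0, 30),
        ]
    )
    n_contigs_per_genome: int = 15
    min_contig_len: int = 5000
    read_len: int = 100
    error_rate: float = 0.02
    k_bins: int = 3
    recruit_min_len: int = 50
    recruit_min_identity: float = 95.0
    ani_fragment: int = 1020
    mean_spacer: float = 20.0
    gc_spread_flag: float = 0.02  # within-bin GC sd above this flags under-clustering

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        genomes = [GenomeSpec(**g) for g in raw.pop("genomes", [])]
        cfg = cls(**raw)
        if genomes:
            cfg.genomes = genomes
        return cfg


def run_end_to_end(config: RunConfig) -> dict[str, Any]:
    """Run simulate -> bin -> completeness -> recruit -> stats; return report."""
    marker_set = MarkerSet.bundled("set35")
    try:
        genomes = [
            sc.generate_genome(
                g.length,
                g.gc,
                seed=config.seed + _STAGE_GENOMES + 1000 * i,
                genome_id=g.id,
                markers=marker_set.markers[: g.n_markers],
            )
            for i, g in enumerate(config.genomes)
        ]
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise RuntimeError(f"stage 'simulate genomes' failed: {exc}") from exc

    spec_by_id = {g.id: g for g in config.genomes}
    try:
        contigs: list[cb.ContigRecord] = []
        for i, g in enumerate(genomes):
            contigs.extend(
                sc.fragment_genome(
                    g,
                    n_contigs=config.n_contigs_per_genome,
                    min_len=config.min_contig_len,
                    seed=config.seed + _STAGE_CONTIGS + 1000 * i,
                    coverage={"sample1": spec_by_id[g.id].coverage},
                )
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'fragment contigs' failed: {exc}") from exc

    try:
        reads = sc.simulate_reads(
            genomes,
            coverages={g.id: spec_by_id[g.id].coverage for g in genomes},
            read_len=config.read_len,
            error_rate=config.error_rate,
            seed=config.seed + _STAGE_READS,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate reads' failed: {exc}") from exc

    try:
        features = cb.compute_features(contigs, min_len=config.min_contig_len)
        bins = cb.bin_contigs(
            features, contigs, k=config.k_bins, seed=config.seed + _STAGE_BINNING
        )
        accuracy = cb.binning_accuracy(bins, contigs)
    except Exception as exc:
        raise RuntimeError(f"stage 'composition binning' failed: {exc}") from exc

    # match each bin to the genome contributing most of its contigs
    contig_src = {c.id: c.source_genome for c in contigs}
    completeness_report: dict[str, Any] = {}
    underclustering_flags: dict[str, bool] = {}
    genome_by_id = {g.id: g for g in genomes}
    for b in bins:
        src_counts: dict[str, int] = {}
        for cid in b.contig_ids:
            src = contig_src.get(cid)
            if src:
                src_counts[src] = src_counts.get(src, 0) + 1
        majority = max(sorted(src_counts), key=lambda s: src_counts[s])
        genome = genome_by_id[majority]
        members = [c for c in contigs if c.id in set(b.contig_ids)]
        hits = sc.markers_in_contigs(
            genome, [c for c in members if c.source_genome == genome.id]
        )
        rep = marker_completeness.completeness_report(hits, marker_set, b.total_bp)
        gcs = [c.gc for c in members]
        gc_sd = float(np.std(gcs)) if len(gcs) > 1 else 0.0
        underclustering_flags[b.bin_id] = gc_sd > config.gc_spread_flag
        completeness_report[b.bin_id] = {
            "matched_genome": majority,
            "markers_found": rep.markers_found,
            "markers_total": rep.markers_total,
            "completeness_pct": rep.completeness_pct,
            "assembled_bp": rep.assembled_bp,
            "estimated_mb": rep.estimated_mb,
            "true_genome_mb": round(len(genome.sequence) / 1e6, 2),
            "within_bin_gc_sd": round(gc_sd, 4),
        }

    try:
        read_records = [r.as_seqrecord() for r in reads]
        rpkg_per_genome = {}
        for g in genomes:
            res = recruitment.recruit(
                read_records,
                SeqRecord(id=g.id, description="", sequence=g.sequence),
                min_len=config.recruit_min_len,
                min_identity=config.recruit_min_identity,
            )
            rpkg_per_genome[g.id] = {
                "reads_recruited": res.reads_recruited,
                "rpkg": round(res.rpkg, 2),
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'fragment recruitment' failed: {exc}") from exc

    try:
        ani_matrix: dict[str, dict[str, float | None]] = {}
        for ga in genomes:
            ani_matrix[ga.id] = {}
            for gb in genomes:
                if gb.id <= ga.id:
                    continue
                res = genome_stats.ani(
                    ga.sequence, gb.sequence, fragment=config.ani_fragment
                )
                ani_matrix[ga.id][gb.id] = (
                    None if np.isnan(res.ani) else round(res.ani, 2)
                )
    except Exception as exc:
        raise RuntimeError(f"stage 'ANI' failed: {exc}") from exc

    try:
        genes = sc.annotate_genes(
            genomes[0], mean_spacer=config.mean_spacer,
            seed=config.seed + _STAGE_GENES,
        )
        spacers = genome_stats.intergenic_spacers(genes)
    except Exception as exc:
        raise RuntimeError(f"stage 'spacer statistics' failed: {exc}") from exc

    return {
        "seed": config.seed,
        "thresholds": {
            "min_contig_len": config.min_contig_len,
            "k_bins": config.k_bins,
            "recruit_min_len": config.recruit_min_len,
            "recruit_min_identity": config.recruit_min_identity,
            "ani_fragment": config.ani_fragment,
            "error_rate": config.error_rate,
            "read_len": config.read_len,
        },
        "community": {
            g.id: {"length": g.length, "gc": g.gc, "coverage": g.coverage}
            for g in config.genomes
        },
        "n_contigs": len(contigs),
        "n_reads": len(reads),
        "binning_accuracy_pct": round(100.0 * accuracy, 2),
        "bins": completeness_report,
        "underclustering_flags": underclustering_flags,
        "rpkg": rpkg_per_genome,
        "ani_matrix": ani_matrix,
        "spacers": {
            "median_bp": spacers.median,
            "mean_bp": round(spacers.mean, 2),
            "n_pairs": spacers.n_pairs,
        },
    }


def report_to_json(report: dict[str, Any]) -> str:
    """Canonical serialization: sorted keys, fixed separators (byte-stable)."""
    return json.dumps(report, sort_keys=True, indent=2)
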