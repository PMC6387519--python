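"""Cohort orchestration: detection through annotation over a manifest.

A cohort is described by a manifest TSV with columns organism_id, fasta, gff
(optional, empty to skip annotation), group, subgroup, order_index. The
pipeline scans each genome, computes genome and per-class attributes, builds
the enrichment score matrix, tests subgroup signatures, detects
length-preference peaks, annotates SSRs where a GFF is given, and writes one
tidy TSV/JSON per product. Outputs are deterministic: rerunning the same
configuration reproduces every file byte for byte, and reordering manifest
rows only permutes rows of the outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import annotate_records, build_feature_index, region_composition
from .attributes import (
    ATTRIBUTE_CONVENTIONS,
    master_table,
    per_class_stats,
    summarize_genome,
)
from .detect import DEFAULT_MAX_K, DEFAULT_MIN_LENGTH, scan_fasta, write_bed
from .lengths import class_length_medians, cohort_peaks, preference_prevalence, top_n_longest
from .ranking import build_score_matrix, cluster_classes, export_heatmap_json, scan_signatures

MANIFEST_COLUMNS = ("organism_id", "fasta", "gff", "group", "subgroup", "order_index")


class PipelineError(RuntimeError):
    """A stage failed; the message names the organism and stage."""


@dataclass
class CohortConfig:
    manifest_path: str | Path
    output_dir: str | Path
    min_length: int = DEFAULT_MIN_LENGTH
    max_k: int = DEFAULT_MAX_K
    seed: int = 0
    linkage_method: str = "average"
    alpha: float = 0.05
    bonferroni: bool = True
    top_longest: int = 100
    median_top_n: int = 1000
    extra_settings: dict = field(default_factory=dict)


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype={"gff": str}, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise PipelineError(f"manifest missing columns {missing}")
    if manifest["organism_id"].duplicated().any():
        raise PipelineError("duplicate organism ids in manifest")
    return manifest.sort_values("order_index").reset_index(drop=True)


def run_cohort(config: CohortConfig) -> dict[str, Path]:
    """Run every stage over the manifest; returns the paths written."""
    manifest = read_manifest(config.manifest_path)
    base = Path(config.manifest_path).parent
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    summaries = []
    class_tables = []
    records_by_org = {}
    annotated_frames = []
    for row in manifest.itertuples():
        org = row.organism_id
        try:
            records, stats = scan_fasta(
                base / row.fasta, config.min_length, config.max_k
            )
        except Exception as exc:
            raise PipelineError(f"{org}: detection failed: {exc}") from exc
        records_by_org[org] = records
        bed_path = out / f"{org}.ssrs.bed"
        write_bed(records, bed_path)
        written[f"bed:{org}"] = bed_path
        try:
            summary = summarize_genome(records, stats, org)
            summaries.append(summary)
            class_tables.append(
                per_class_stats(records, summary.genome_size_bp, org, config.max_k)
            )
        except Exception as exc:
            raise PipelineError(f"{org}: attributes failed: {exc}") from exc
        if row.gff:
            try:
                index = build_feature_index(base / row.gff)
                annotated = annotate_records(records, index)
                annotated.insert(0, "organism_id", org)
                annotated_frames.append(annotated)
                ann_path = out / f"{org}.annotated.tsv"
                annotated.to_csv(ann_path, sep="\t", index=False)
                written[f"annotated:{org}"] = ann_path
            except Exception as exc:
                raise PipelineError(f"{org}: annotation failed: {exc}") from exc

    organism_table = manifest[["organism_id", "group", "subgroup"]]
    master = master_table(summaries, organism_table)
    master_path = out / "master_table.tsv"
    with open(master_path, "w") as handle:
        for key, value in ATTRIBUTE_CONVENTIONS.items():
            handle.write(f"# {key}: {value}\n")
        master.to_csv(handle, sep="\t", index=False)
    written["master_table"] = master_path

    cohort_stats = pd.concat(class_tables, ignore_index=True)
    per_class_path = out / "per_class_stats.tsv"
    cohort_stats.to_csv(per_class_path, sep="\t", index=False)
    written["per_class_stats"] = per_class_path

    try:
        matrix = build_score_matrix(cohort_stats, list(manifest["organism_id"]))
        heatmap_path = out / "score_matrix.json"
        export_heatmap_json(matrix, heatmap_path)
        written["score_matrix"] = heatmap_path
        order, _ = cluster_classes(matrix, config.linkage_method)
        order_path = out / "class_cluster_order.txt"
        order_path.write_text("\n".join(order) + "\n")
        written["class_cluster_order"] = order_path
    except Exception as exc:
        raise PipelineError(f"cohort: scoring failed: {exc}") from exc

    clades = {
        sg: list(sub["organism_id"])
        for sg, sub in manifest.groupby("subgroup")
        if 0 < len(sub) < len(manifest) - 1
    }
    signatures = scan_signatures(
        cohort_stats, clades, alpha=config.alpha, bonferroni=config.bonferroni
    )
    sig_path = out / "signatures.tsv"
    signatures.to_csv(sig_path, sep="\t", index=False)
    written["signatures"] = sig_path

    peaks = cohort_peaks(records_by_org)
    peaks_path = out / "length_preference_peaks.tsv"
    peaks.to_csv(peaks_path, sep="\t", index=False)
    written["peaks"] = peaks_path
    subgroup_of = dict(zip(manifest["organism_id"], manifest["subgroup"]))
    prevalence = preference_prevalence(peaks, subgroup_of)
    prev_path = out / "preference_prevalence.tsv"
    prevalence.to_csv(prev_path, sep="\t")
    written["prevalence"] = prev_path

    longest_rows = []
    for org, records in records_by_org.items():
        for r in top_n_longest(records, config.top_longest):
            longest_rows.append(
                {
                    "organism_id": org,
                    "seq_id": r.seq_id,
                    "start": r.start,
                    "end": r.end,
                    "repeat_class": r.repeat_class,
                    "length_bp": r.length_bp,
                }
            )
    longest = pd.DataFrame(
        longest_rows,
        columns=["organism_id", "seq_id", "start", "end", "repeat_class", "length_bp"],
    )
    longest_path = out / "longest_instances.tsv"
    longest.to_csv(longest_path, sep="\t", index=False)
    written["longest_instances"] = longest_path

    median_rows = []
    for org, records in records_by_org.items():
        medians = class_length_medians(records, config.median_top_n)
        for cls, value in medians.items():
            median_rows.append(
                {"organism_id": org, "repeat_class": cls, "median_length_bp": value}
            )
    medians_df = pd.DataFrame(
        median_rows, columns=["organism_id", "repeat_class", "median_length_bp"]
    )
    medians_path = out / "class_length_medians.tsv"
    medians_df.to_csv(medians_path, sep="\t", index=False)
    written["class_length_medians"] = medians_path

    if annotated_frames:
        all_annotated = pd.concat(annotated_frames, ignore_index=True)
        composition = region_composition(all_annotated)
        comp_path = out / "region_composition.tsv"
        composition.to_csv(comp_path, sep="\t")
        written["region_composition"] = comp_path

    log = {
        "ssrscape_version": __version__,
        "min_length": config.min_length,
        "max_k": config.max_k,
        "seed": config.seed,
        "linkage_method": config.linkage_method,
        "alpha": config.alpha,
        "bonferroni": config.bonferroni,
        "coordinate_convention": "0-based half-open (BED)",
        "overlap_resolution": "left-to-right greedy, longest run first, "
        "ties to smaller motif size",
        "n_handling": "N breaks repeats; genome size includes N; genomic GC "
        "over non-N bases",
        "conventions": ATTRIBUTE_CONVENTIONS,
        **config.extra_settings,
    }
    log_path = out / "run_log.json"
    with open(log_path, "w") as handle:
        json.dump(log, handle, indent=1, sort_keys=True)
    written["run_log"] = log_path
    return written
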