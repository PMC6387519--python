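"""Genomic-feature annotation of SSRs from GFF3 gene models.

Each SSR is assigned to exon, intron or intergenic space. Gene bodies come
from ``gene`` feature rows; exon intervals are pooled across isoforms and
merged, and introns are derived as gene body minus merged exons, so
alternative transcripts never double-count. Intergenic space is the
complement of merged gene spans. Assignment precedence for repeats spanning
a boundary is exon > intron > intergenic on any overlap; the per-record
exon-overlap percentage keeps that choice auditable. The distance to the
nearest transcription start site (TSS: the gene's 5' end with respect to its
strand) is measured unsigned from the nearest SSR boundary, 0 if the SSR
covers the TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .detect import SSRRecord

logger = logging.getLogger(__name__)

REGIONS = ("exon", "intron", "intergenic")


class GFFError(ValueError):
    """Malformed GFF3 input."""


@dataclass
class FeatureIndex:
    """Per-contig interval sets derived from a GFF3 annotation.

    ``exons`` / ``introns`` / ``genes`` map seq_id to IntervalTrees of
    0-based half-open intervals; ``tss`` maps seq_id to a sorted array of
    TSS positions.
    """

    genes: dict[str, IntervalTree]
    exons: dict[str, IntervalTree]
    introns: dict[str, IntervalTree]
    tss: dict[str, np.ndarray]


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _subtract(span: tuple[int, int], blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """span minus a sorted list of disjoint blocks."""
    out = []
    cursor = span[0]
    for bs, be in blocks:
        if bs > cursor:
            out.append((cursor, bs))
        cursor = max(cursor, be)
    if cursor < span[1]:
        out.append((cursor, span[1]))
    return out


def build_feature_index(gff_path) -> FeatureIndex:
    """Parse a GFF3 file into merged gene/exon/intron/TSS interval sets.

    NCBI-dialect rows that are not gene or exon features (region, pseudogene,
    mRNA, CDS, ...) are ignored for region derivation. Genes without exon
    children are treated as single-exon genes. Exons poking outside their
    gene span are clipped with a warning.
    """
    with open(gff_path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GFFError(
                    f"{gff_path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            if not (fields[3].isdigit() and fields[4].isdigit()):
                raise GFFError(
                    f"{gff_path}: line {lineno}: non-numeric coordinates"
                )
    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise GFFError(f"failed to parse GFF3 {gff_path}: {exc}") from exc

    genes: dict[str, list[tuple[int, int]]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    introns: dict[str, list[tuple[int, int]]] = {}
    tss: dict[str, list[int]] = {}

    for gene in db.features_of_type("gene"):
        # GFF3 is 1-based inclusive; convert to 0-based half-open
        g_start, g_end = gene.start - 1, gene.end
        if g_end <= g_start:
            raise GFFError(f"gene {gene.id} has non-positive span")
        seq = gene.seqid
        genes.setdefault(seq, []).append((g_start, g_end))
        tss.setdefault(seq, []).append(g_start if gene.strand != "-" else g_end - 1)
        gene_exons = []
        for exon in db.children(gene, featuretype="exon"):
            e_start, e_end = exon.start - 1, exon.end
            if e_start < g_start or e_end > g_end:
                logger.warning(
                    "exon %s outside gene %s span; clipping", exon.id, gene.id
                )
                e_start, e_end = max(e_start, g_start), min(e_end, g_end)
            if e_end > e_start:
                gene_exons.append((e_start, e_end))
        if not gene_exons:
            logger.info("gene %s has no exon children; treating as single-exon", gene.id)
            gene_exons = [(g_start, g_end)]
        merged_exons = _merge_intervals(gene_exons)
        exons.setdefault(seq, []).extend(merged_exons)
        introns.setdefault(seq, []).extend(_subtract((g_start, g_end), merged_exons))

    def _trees(d: dict[str, list[tuple[int, int]]]) -> dict[str, IntervalTree]:
        return {
            seq: IntervalTree.from_tuples(_merge_intervals(iv))
            for seq, iv in d.items()
            if iv
        }

    return FeatureIndex(
        genes=_trees(genes),
        exons=_trees(exons),
        introns=_trees(introns),
        tss={seq: np.array(sorted(v), dtype=np.int64) for seq, v in tss.items()},
    )


@dataclass(frozen=True)
class AnnotationRecord:
    """An SSR plus its genomic context."""

    record: SSRRecord
    region: str  # exon | intron | intergenic
    exon_overlap_pct: float | None  # only for exonic records
    tss_distance: int | None  # None when the contig has no genes


def _overlap_bases(tree: IntervalTree | None, start: int, end: int) -> int:
    if tree is None:
        return 0
    return sum(min(iv.end, end) - max(iv.begin, start) for iv in tree.overlap(start, end))


def annotate_record(
    ssr: SSRRecord, index: FeatureIndex, missing_seq_ok: bool = True
) -> AnnotationRecord:
    """Assign one SSR to exon/intron/intergenic and measure TSS distance.

    A contig absent from the annotation yields an intergenic call with a
    warning (or an error when ``missing_seq_ok`` is False).
    """
    seq = ssr.seq_id
    if seq not in index.genes and seq not in index.tss:
        if not missing_seq_ok:
            raise KeyError(f"sequence {seq!r} not in annotation")
        logger.warning("sequence %s absent from annotation; calling intergenic", seq)
        return AnnotationRecord(ssr, "intergenic", None, None)
    exon_bases = _overlap_bases(index.exons.get(seq), ssr.start, ssr.end)
    if exon_bases > 0:
        region = "exon"
        overlap_pct = 100.0 * exon_bases / ssr.length_bp
    elif _overlap_bases(index.introns.get(seq), ssr.start, ssr.end) > 0:
        region, overlap_pct = "intron", None
    else:
        region, overlap_pct = "intergenic", None
    positions = index.tss.get(seq)
    if positions is None or len(positions) == 0:
        distance = None
    else:
        last = ssr.end - 1
        left = positions[positions < ssr.start]
        right = positions[positions > last]
        candidates = []
        if np.any((positions >= ssr.start) & (positions <= last)):
            candidates.append(0)
        if len(left):
            candidates.append(int(ssr.start - left.max()))
        if len(right):
            candidates.append(int(right.min() - last))
        distance = min(candidates)
    return AnnotationRecord(ssr, region, overlap_pct, distance)


def annotate_records(
    records: Sequence[SSRRecord], index: FeatureIndex
) -> pd.DataFrame:
    """Annotate a batch of SSRs; one row per record."""
    rows = []
    for r in records:
        ann = annotate_record(r, index)
        rows.append(
            {
                "seq_id": r.seq_id,
                "start": r.start,
                "end": r.end,
                "repeat_class": r.repeat_class,
                "actual_motif": r.actual_motif,
                "k": r.k,
                "length_bp": r.length_bp,
                "units": r.units,
                "region": ann.region,
                "exon_overlap_pct": ann.exon_overlap_pct,
                "tss_distance": ann.tss_distance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "start",
            "end",
            "repeat_class",
            "actual_motif",
            "k",
            "length_bp",
            "units",
            "region",
            "exon_overlap_pct",
            "tss_distance",
        ],
    )


def region_composition(annotated: pd.DataFrame) -> pd.DataFrame:
    """Motif-size composition of SSR bases per region and overall.

    For each region (and the whole genome), the percentage of SSR bases
    contributed by each motif size 1..6; each row sums to 100. Regions with
    zero SSR bases are omitted.
    """
    if annotated.empty:
        raise ValueError("no annotated records")
    frames = {}
    groups = [("all", annotated)] + [
        (region, annotated[annotated["region"] == region]) for region in REGIONS
    ]
    for name, sub in groups:
        total = sub["length_bp"].sum()
        if total == 0:
            continue
        by_k = sub.groupby("k")["length_bp"].sum()
        frames[name] = {
            k: 100.0 * by_k.get(k, 0) / total for k in range(1, 7)
        }
    table = pd.DataFrame(frames).T
    table.index.name = "region"
    table.columns = [f"k{k}" for k in range(1, 7)]
    return table
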