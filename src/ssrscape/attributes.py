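"""Per-genome and per-class SSR summary attributes.

The master-table quantities used throughout the pipeline: SSR frequency
(count of repeats), base coverage (summed repeat lengths), density (bases
covered per Mb of genome) and SSR GC% (GC of the concatenation of all repeat
sequences). Genome size counts N bases; genomic GC is computed over non-N
bases only. Both conventions are recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .detect import SSRRecord, SequenceStats
from .motifs import class_order, tandem_expansion

#: Conventions baked into every summary; exported with the master table.
ATTRIBUTE_CONVENTIONS = {
    "genome_size": "total assembly length including N bases",
    "genomic_gc": "GC fraction of non-N bases",
    "ssr_gc": "GC fraction of the concatenation of all repeat sequences",
    "density_units": "bp covered by SSRs per Mb of genome",
}


@dataclass(frozen=True)
class GenomeSummary:
    organism_id: str
    genome_size_bp: int
    genomic_gc_fraction: float
    ssr_frequency: int
    ssr_bases: int
    ssr_density: float
    ssr_gc_fraction: float | None  # None when the genome has no SSRs


def _record_gc_bases(record: SSRRecord) -> int:
    # GC of the repeat slice, reconstructed from the motif: full units plus
    # the partial trailing unit.
    window = tandem_expansion(record.actual_motif, record.length_bp)
    return window.count("G") + window.count("C")


def summarize_genome(
    records: Sequence[SSRRecord],
    stats: Sequence[SequenceStats],
    organism_id: str,
) -> GenomeSummary:
    """Genome-level SSR attributes from detected records and sequence stats."""
    if not stats:
        raise ValueError(f"{organism_id}: no sequences — empty genome")
    genome_size = sum(s.length_bp for s in stats)
    if genome_size == 0:
        raise ValueError(f"{organism_id}: zero-length genome")
    known = {s.seq_id for s in stats}
    stray = {r.seq_id for r in records} - known
    if stray:
        raise ValueError(f"{organism_id}: records on unknown sequences {sorted(stray)}")
    informative = sum(s.length_bp - s.n_count for s in stats)
    genomic_gc = (
        sum((s.length_bp - s.n_count) * s.gc_fraction for s in stats) / informative
        if informative
        else 0.0
    )
    ssr_bases = sum(r.length_bp for r in records)
    ssr_gc = (
        sum(_record_gc_bases(r) for r in records) / ssr_bases if ssr_bases else None
    )
    return GenomeSummary(
        organism_id=organism_id,
        genome_size_bp=genome_size,
        genomic_gc_fraction=genomic_gc,
        ssr_frequency=len(records),
        ssr_bases=ssr_bases,
        ssr_density=ssr_bases / genome_size * 1e6,
        ssr_gc_fraction=ssr_gc,
    )


def per_class_stats(
    records: Sequence[SSRRecord],
    genome_size: int,
    organism_id: str,
    max_k: int = 6,
) -> pd.DataFrame:
    """Frequency, bases and density per repeat class, zero-filled.

    One row per class in the stable class order (all 501 for max_k = 6),
    columns: organism_id, repeat_class, frequency, bases, density.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    order = class_order(max_k)
    freq = dict.fromkeys(order, 0)
    bases = dict.fromkeys(order, 0)
    for r in records:
        freq[r.repeat_class] += 1
        bases[r.repeat_class] += r.length_bp
    return pd.DataFrame(
        {
            "organism_id": organism_id,
            "repeat_class": order,
            "frequency": [freq[c] for c in order],
            "bases": [bases[c] for c in order],
            "density": [bases[c] / genome_size * 1e6 for c in order],
        }
    )


def master_table(
    summaries: Iterable[GenomeSummary],
    organism_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per organism: taxonomy columns (if given) + genome attributes.

    ``organism_table`` carries organism_id, group, subgroup (and anything
    else); it is left-joined on organism_id.
    """
    rows = pd.DataFrame(
        [
            {
                "organism_id": s.organism_id,
                "genome_size_bp": s.genome_size_bp,
                "genomic_gc_fraction": s.genomic_gc_fraction,
                "ssr_frequency": s.ssr_frequency,
                "ssr_bases": s.ssr_bases,
                "ssr_density": s.ssr_density,
                "ssr_gc_fraction": s.ssr_gc_fraction,
            }
            for s in summaries
        ]
    )
    if organism_table is not None:
        tax_cols = [c for c in organism_table.columns if c != "organism_id"]
        rows = organism_table[["organism_id", *tax_cols]].merge(
            rows, on="organism_id", how="right"
        )
    return rows
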