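"""Per-genome SSR attributes: frequency, coverage, density, SSR GC%.

Density (bases covered by SSRs per Mb of genome) is the normalization used
for all cross-species comparisons; SSR GC% is the GC of the concatenation of
all repeat sequences.
"""

from ssrscape import (
    PlantedRepeat,
    SyntheticGenomeSpec,
    generate_genome,
    per_class_stats,
    scan_sequence,
    sequence_stats,
    summarize_genome,
)

spec = SyntheticGenomeSpec(
    "demo", 200_000, background_gc=0.45, rng_seed=3,
    planted=[PlantedRepeat("AC", 40), PlantedRepeat("AC", 24),
             PlantedRepeat("AAG", 30), PlantedRepeat("A", 25),
             PlantedRepeat("AGGGTT", 60)],
)
genome = generate_genome(spec)
records = scan_sequence("chr1", genome.sequence)
stats = [sequence_stats("chr1", genome.sequence)]

summary = summarize_genome(records, stats, "demo")
print(f"genome size : {summary.genome_size_bp:,} bp")
print(f"SSR count   : {summary.ssr_frequency}")
print(f"SSR bases   : {summary.ssr_bases} bp")
print(f"SSR density : {summary.ssr_density:.1f} bp/Mb")
print(f"SSR GC      : {summary.ssr_gc_fraction:.3f}")

table = per_class_stats(records, summary.genome_size_bp, "demo")
print("\nnon-empty classes:")
print(table[table["frequency"] > 0].to_string(index=False))
# The per-class rows always sum back to the genome totals — the conservation
# property every downstream table relies on.
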