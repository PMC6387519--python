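# Methods

This note documents the model, the conventions and the deliberately made
design choices behind `ssrscape`, and what the synthetic-data tests do and
do not demonstrate about real genomes.

## Repeat classes

A perfect SSR is a tandem repetition of a primitive 1–6 nt motif. Two
motifs describe the same repeat if one is a cyclic rotation of the other or
of its reverse complement; the canonical class representative is the
lexicographic minimum over the ≤ 2k candidate strings (k rotations of the
motif and k of its reverse complement). This yields 5356 primitive motifs
and 501 classes (2, 4, 10, 33, 102 and 350 for motif sizes 1–6), verified
in the test suite against a brute-force orbit enumeration over all 4^k
strings. Enumeration order (motif size ascending, then lexicographic) is
fixed so that every downstream matrix shares one column order.

The GC category of a class is computed on the 12 bp string formed by
repeating the canonical motif in tandem — 12 bp being the minimum repeat
length — not on the motif itself. The two differ for pentamers, where the
12 bp window truncates the third unit (AACGC: motif GC 3/5, window GC
6/12). With a fixed denominator of 12 the five categories reduce to integer
GC counts: ≤ 3 → ≤ 25%; 4–5 → 26–49%; 6 → 50%; 7–8 → 51–74%; ≥ 9 → ≥ 75%.
The computed class-level distribution is 70 / 120 / 133 / 108 / 70.

## Detection

The scanner reports maximal perfect runs with total length ≥ `min_length`
(default 12 bp, i.e. at least two complete hexamer units; a uniform cutoff
across motif sizes means partial trailing units must count toward the
length, so a 14 bp AAAT stretch has length 14 and 3 complete units).
Coordinates are 0-based half-open (BED). Input is uppercased, so
soft-masked repeats are counted; N and all other IUPAC ambiguity codes
match nothing and therefore break runs; characters outside the IUPAC set
are an error.

Overlap resolution, where two motif sizes could claim the same bases, is
left-to-right greedy: at each position the longest maximal run starting
there wins, ties between motif sizes go to the smaller k, the record is
emitted if long enough, and scanning resumes at its end. This rule is
deterministic, order-independent, and guarantees primitivity of every
emitted motif (a run explained by a shorter period is always claimed at the
smaller motif size, which ties or wins). A junction such as (AC)n followed
by poly-A is resolved by greedy extension of the left run, including the
first A as a partial unit; the remaining poly-A is reported separately if
it still clears the cutoff. The same rule is implemented independently in
the test oracle (plain string operations, no shared code) and the two
agree exactly on random and repeat-rich sequences.

Internally the scanner vectorizes the per-position maximal extension with
numpy (for each period k, a boolean match-at-lag-k array and its run
lengths), so scanning is linear in sequence length with small constants;
sequences are processed one at a time so memory tracks the longest contig.

## Genome attributes

Genome size includes N bases (assembly length); genomic GC is computed over
non-N bases only; both conventions are stated in the master-table header
and run log. SSR density is bases covered per Mb of genome. SSR GC is the
GC of the concatenation of all repeat sequences, reconstructed from each
record's motif and length rather than by re-reading the FASTA. A genome
with zero SSRs reports a missing SSR GC rather than zero so correlation
analyses are not distorted. Per-class tables always carry all 501 rows,
zero-filled, in the stable class order, and their totals reconcile exactly
with the genome summary (asserted in tests and across pipeline output
files).

## Enrichment scoring and signatures

Classes are ranked per organism by density, descending; ties are broken by
frequency (descending) then class name, making the ranking a deterministic
permutation. Scores: rank ≤ 10 → 3; ≤ 25 → 2; ≤ 100 → 1; bottom 100 ranks
(402–501 of the full ranking) → −1; frequency < 10 → −2 regardless of rank
(rare classes carry too much sampling noise for their density rank to be
meaningful); else 0. Scores are invariant to rescaling all densities and to
shifting all frequencies above the cutoff.

Column clustering uses Euclidean distance and average linkage by default
(configurable); the linkage choice affects only display order, never the
scores, so nothing downstream depends on it. The clustering is checked
against a hand-written O(n³) agglomerative reference on small matrices.

A class is *uniquely abundant* in a clade when it is top-10 in every member
and in no outsider. Significance uses a two-sided Welch (unequal-variance)
t-test on the class's densities, clade vs all other organisms — densities,
not ranks, carry the effect size being claimed. When several candidate
classes are tested across clades, a Bonferroni correction over the
uniquely-abundant candidates is applied (configurable). Zero-variance
degenerate inputs report a missing p with the rank criterion still
evaluated.

## Length preference

Abundance is the count of SSRs at an exact complete-unit length (the
`units` field); bp-binned histograms are not used because the bump
definition is phrased over consecutive unit lengths. The scan walks the
histogram (missing unit lengths inside the observed range filled with
zeros; zero-count entries beyond it trimmed, so padding can never
manufacture an endpoint): the unit before the first rise is the peak start;
a plateau does not count as a rise; the endpoint is the first unit where
abundance falls strictly below the start abundance; a bump with no such
endpoint before the histogram ends is discarded. Kept bumps must span ≥ 4
consecutive unit lengths (start and end inclusive) and start above
abundance 10. Scanning resumes just past each bump's endpoint, so multiple
disjoint bumps are reported. The strict-lower endpoint comparison is a
documented choice; the hand-traced worked histograms in the tests pin the
exact (start, maximum, end) triples.

## Annotation

Gene bodies come from `gene` rows only; mRNA/transcript rows are ignored
and exons are pooled across isoforms and merged before introns are derived
as gene minus exons, so alternative transcripts never double-count. Genes
without exon children are treated as single-exon genes. Intergenic space is
the complement of merged gene spans. Region precedence for
boundary-spanning SSRs is exon > intron > intergenic on any overlap; the
reported exon-overlap percentage keeps that choice auditable (on synthetic
data with repeats planted wholly inside exons, every exonic record overlaps
100%). TSS positions are the gene's 5′ end by strand; distance is unsigned,
measured from the nearest SSR boundary, zero if the repeat covers the TSS,
and missing on contigs without genes.

## Synthetic data

The generator emulates exactly the statistical structure the analyses
assume and nothing more. Background sequence is i.i.d. at the requested GC
(realized GC concentrates within ±0.01 at 1 Mb); any incidental ≥ 12 bp
perfect repeat in the background is broken by a point substitution
(scan-and-break was chosen over constrained sampling because it is simple
and directly verifiable). Planted arrays are written verbatim with guard
bases at both flanks chosen to break period-k extension, and a final
re-scan repairs any repeat incidentally created at an array/background
junction, editing only background bases. The resulting guarantee — the
detector's record set equals the truth table exactly — is what makes all
downstream end-to-end tests exact rather than approximate.

Cohorts plant a shared baseline of ~30 repeat classes with per-organism
Poisson/length noise (arrays 12–40 bp), a signature class per clade (~40–45
arrays of ~45 bp with geometrically decaying lengths, roughly 10× the
densest baseline class, so the class is top-10 in members and absent
elsewhere), and explicit unit-length histograms for planted
length-preference bumps. Default cohort genomes are 120 kb at GC 0.42;
sizes were chosen so a full multi-organism cohort generates and analyses in
seconds while every planted effect is far above the detection thresholds.
For power and false-positive studies that need hundreds of replicates,
`simulate_cohort_stats` samples the same cross-organism structure directly
at the class-statistics level (shared lognormal class scales, ~half the
classes rare, per-organism lognormal noise, signatures planted at a
configurable fold over the organism's 10th-highest density), skipping
sequence generation entirely.

What passing these tests shows: the algorithms are implemented correctly
against their definitions, exactly recover planted effects, and control
false positives on null cohorts. What they do not show: real genomes are
not i.i.d. backgrounds with isolated perfect arrays — they contain
imperfect and compound repeats, assembly artifacts (e.g. spurious long C/G
stretches), and correlated repeat families. Conclusions about real data
still require the usual per-genome quality scrutiny.

## Numerical and degenerate-input choices

Rank ties, clustering tie-breaks and enumeration orders are all fixed so
that every output is deterministic; the pipeline's outputs are
byte-identical across reruns with the same seed, and manifest order only
permutes rows. Empty genomes and clades that are not proper subsets raise;
zero-SSR genomes, zero-variance tests and annotation-free contigs report
missing values instead of fabricated zeros. All randomness in the
synthetic-data module flows from explicit integer seeds.

## Known limitations

Imperfect and compound repeats are out of scope (the detector is exact by
design); motifs longer than 6 nt are not considered; annotation does not
sub-classify UTR/CDS or promoter windows; the heatmap export is a matrix
file for external viewers, not a rendered figure.
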