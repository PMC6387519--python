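"""Synthetic genomes, annotations and cohorts with known ground truth.

Every analysis stage in this package is exercised against data whose answer
is known by construction. The generator builds i.i.d. background sequence at
a chosen GC content, scrubs it until it is free of perfect repeats at the
detection threshold (any incidental >= 12 bp run is broken by a point
substitution), then overwrites planted tandem arrays at non-overlapping
positions with guard bases at both flanks so each array is exactly maximal.
A final validation pass re-scans the genome and repairs any repeat created
at an array/background junction, so the detector's output on a generated
genome equals the truth table exactly.

Cohorts add the cross-organism structure the comparative analyses assume: a
shared baseline set of repeat classes with per-organism density noise, a
boosted "signature" class for each planted clade, and unit-length abundance
bumps for organisms planted with a length preference. For statistical
power/false-positive studies that need hundreds of replicates, the same
cohort structure can also be sampled directly at the class-statistics level
(:func:`simulate_cohort_stats`), skipping sequence generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import DEFAULT_MIN_LENGTH, SSRRecord, scan_sequence
from .motifs import ALPHABET, canonical_class, class_order, is_primitive

_CONTIG = "chr1"
_MAX_REPAIR_ROUNDS = 200


@dataclass(frozen=True)
class PlantedRepeat:
    """One tandem array to embed: motif as it should read at the start."""

    motif: str
    length_bp: int
    position: int | None = None  # None = place at random, non-overlapping


@dataclass(frozen=True)
class GeneModel:
    """A toy gene for the GFF3 output: span, strand, exon blocks (0-based half-open)."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()


@dataclass
class SyntheticGenomeSpec:
    organism_id: str
    genome_length: int
    background_gc: float = 0.5
    rng_seed: int = 0
    planted: list[PlantedRepeat] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    subgroup: str = "default"


@dataclass
class SyntheticGenome:
    """A generated genome plus its ground truth."""

    spec: SyntheticGenomeSpec
    sequence: str
    truth: pd.DataFrame  # one row per expected SSRRecord, with region

    def write_fasta(self, path) -> None:
        with open(path, "w") as out:
            out.write(f">{_CONTIG} {self.spec.organism_id}\n")
            seq = self.sequence
            for i in range(0, len(seq), 70):
                out.write(seq[i : i + 70] + "\n")

    def write_gff(self, path) -> None:
        with open(path, "w") as out:
            out.write("##gff-version 3\n")
            for g in self.spec.genes:
                attrs = f"ID={g.gene_id}"
                out.write(
                    f"{_CONTIG}\tssrscape\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                for j, (es, ee) in enumerate(g.exons, 1):
                    out.write(
                        f"{_CONTIG}\tssrscape\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                        f"ID={g.gene_id}.e{j};Parent={g.gene_id}\n"
                    )

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def expected_records(self) -> list[SSRRecord]:
        return [
            SSRRecord(
                seq_id=row.seq_id,
                start=int(row.start),
                end=int(row.end),
                repeat_class=row.repeat_class,
                actual_motif=row.actual_motif,
                k=int(row.k),
                length_bp=int(row.length_bp),
                units=int(row.units),
            )
            for row in self.truth.itertuples()
        ]


def _expand(motif: str, length_bp: int) -> str:
    reps = -(-length_bp // len(motif))
    return (motif * reps)[:length_bp]


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    if not 0 < gc < 1:
        raise ValueError("background_gc must be in (0, 1)")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def _scrub_background(
    seq: np.ndarray, rng: np.random.Generator, min_length: int
) -> None:
    """Break every perfect repeat >= min_length by point substitution, in place."""
    for _ in range(_MAX_REPAIR_ROUNDS):
        hits = scan_sequence(_CONTIG, seq.tobytes().decode(), min_length)
        if not hits:
            return
        for rec in hits:
            mid = (rec.start + rec.end) // 2
            seq[mid] = _substitute(rng, seq, mid)
    raise RuntimeError("background scrub did not converge")


def _substitute(rng: np.random.Generator, seq: np.ndarray, pos: int) -> int:
    choices = [b for b in b"ACGT" if b != seq[pos]]
    return int(rng.choice(choices))


def _resolve_positions(
    spec: SyntheticGenomeSpec, rng: np.random.Generator
) -> list[tuple[PlantedRepeat, int]]:
    """Fix a start for every planted array, honouring explicit positions."""
    occupied: list[tuple[int, int]] = []  # guard-inclusive spans

    def conflict(start: int, length: int) -> bool:
        lo, hi = start - 2, start + length + 2
        return any(lo < e and s < hi for s, e in occupied)

    placed: list[tuple[PlantedRepeat, int]] = []
    for p in spec.planted:
        if not is_primitive(p.motif):
            raise ValueError(f"planted motif {p.motif!r} is not primitive")
        if p.length_bp <= len(p.motif):
            raise ValueError(f"planted array shorter than its motif: {p}")
        if p.position is not None:
            if p.position < 1 or p.position + p.length_bp > spec.genome_length - 1:
                raise ValueError(f"planted array out of genome bounds: {p}")
            if conflict(p.position, p.length_bp):
                raise ValueError(f"planted arrays overlap near position {p.position}")
            start = p.position
        else:
            for _ in range(1000):
                start = int(rng.integers(1, spec.genome_length - p.length_bp - 1))
                if not conflict(start, p.length_bp):
                    break
            else:
                raise ValueError("could not place planted arrays without overlap")
        occupied.append((start - 1, start + p.length_bp + 1))
        placed.append((p, start))
    return placed


def _plant(
    seq: np.ndarray, placed: list[tuple[PlantedRepeat, int]], rng: np.random.Generator
) -> None:
    for p, start in placed:
        array = np.frombuffer(_expand(p.motif, p.length_bp).encode(), dtype=np.uint8)
        k, L = len(p.motif), p.length_bp
        seq[start : start + L] = array
        # guard bases: break period-k extension one base out on each side
        left_block = array[k - 1]
        right_block = array[L - k]
        if start >= 1:
            seq[start - 1] = int(rng.choice([b for b in b"ACGT" if b != left_block]))
        if start + L < len(seq):
            seq[start + L] = int(rng.choice([b for b in b"ACGT" if b != right_block]))


def _region_of(start: int, end: int, genes: Sequence[GeneModel]) -> str:
    # same precedence as feature_annotation: exon > intron > intergenic
    in_intron = False
    for g in genes:
        exons = list(g.exons) or [(g.start, g.end)]
        for es, ee in exons:
            if start < ee and es < end:
                return "exon"
        if start < g.end and g.start < end:
            in_intron = True
    return "intron" if in_intron else "intergenic"


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Build the genome described by ``spec``; deterministic given its seed."""
    rng = np.random.default_rng(spec.rng_seed)
    if spec.genome_length < DEFAULT_MIN_LENGTH:
        raise ValueError("genome too short")
    seq = _random_background(rng, spec.genome_length, spec.background_gc)
    _scrub_background(seq, rng, DEFAULT_MIN_LENGTH)
    placed = _resolve_positions(spec, rng)
    _plant(seq, placed, rng)

    expected = []
    for p, start in placed:
        if p.length_bp >= DEFAULT_MIN_LENGTH:
            expected.append(
                SSRRecord(
                    seq_id=_CONTIG,
                    start=start,
                    end=start + p.length_bp,
                    repeat_class=canonical_class(p.motif),
                    actual_motif=p.motif,
                    k=len(p.motif),
                    length_bp=p.length_bp,
                    units=p.length_bp // len(p.motif),
                )
            )
    expected.sort(key=lambda r: r.start)
    _repair_junctions(seq, expected, placed, rng)

    truth = pd.DataFrame(
        [
            {
                "seq_id": r.seq_id,
                "start": r.start,
                "end": r.end,
                "repeat_class": r.repeat_class,
                "actual_motif": r.actual_motif,
                "k": r.k,
                "length_bp": r.length_bp,
                "units": r.units,
                "region": _region_of(r.start, r.end, spec.genes),
            }
            for r in expected
        ],
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
        ],
    )
    return SyntheticGenome(spec=spec, sequence=seq.tobytes().decode(), truth=truth)


def _repair_junctions(
    seq: np.ndarray,
    expected: list[SSRRecord],
    placed: list[tuple[PlantedRepeat, int]],
    rng: np.random.Generator,
) -> None:
    """Re-scan and break any repeat the planting step created incidentally."""
    want = {(r.start, r.end, r.repeat_class) for r in expected}
    protected: list[tuple[int, int]] = [
        (start - 1, start + p.length_bp + 1) for p, start in placed
    ]

    def background_positions(lo: int, hi: int) -> list[int]:
        return [
            i
            for i in range(lo, hi)
            if not any(s <= i < e for s, e in protected)
        ]

    for _ in range(_MAX_REPAIR_ROUNDS):
        got = scan_sequence(_CONTIG, seq.tobytes().decode(), DEFAULT_MIN_LENGTH)
        spurious = [
            r for r in got if (r.start, r.end, r.repeat_class) not in want
        ]
        if not spurious and len(got) == len(want):
            return
        if not spurious:
            raise RuntimeError("expected planted repeat missing after generation")
        edited = False
        for rec in spurious:
            # records with no editable background base are downstream debris of
            # another spurious record (e.g. the remainder of a planted array
            # whose start was swallowed by a junction merge); fixing the
            # editable ones makes them vanish on the next scan
            editable = background_positions(rec.start, rec.end)
            if editable:
                pos = editable[len(editable) // 2]
                seq[pos] = _substitute(rng, seq, pos)
                edited = True
        if not edited:
            raise RuntimeError(
                "cannot repair spurious repeats at "
                + ", ".join(f"{r.start}-{r.end}" for r in spurious)
            )
    raise RuntimeError("junction repair did not converge")


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class PeakPlan:
    """Plant a unit-length abundance bump for one repeat class.

    ``histogram`` maps unit length -> number of arrays planted with exactly
    that many complete units.
    """

    repeat_class: str
    histogram: Mapping[int, int]


def bump_histogram(
    peak_start: int = 4,
    width: int = 5,
    height: int = 30,
    start_abundance: int = 20,
) -> dict[int, int]:
    """A histogram with a guaranteed detectable bump.

    A decaying baseline from unit length 2 down to ``start_abundance`` at
    ``peak_start``, a rise to ``height`` over ``width`` unit lengths, then a
    drop below the start abundance.
    """
    if width < 3:
        raise ValueError("bump width must be >= 3 unit lengths")
    hist: dict[int, int] = {}
    level = max(4 * start_abundance, 50)
    for u in range(2, peak_start):
        hist[u] = level
        level = max(start_abundance + 1, int(level * 0.5))
    hist[peak_start] = start_abundance
    apex = peak_start + max(1, width // 2)
    for u in range(peak_start + 1, peak_start + width):
        dist = abs(u - apex)
        hist[u] = max(start_abundance + 2, height - dist * max(1, height // width))
    hist[peak_start + width] = max(1, start_abundance // 4)
    return hist


@dataclass
class CohortPlan:
    """Cross-organism structure for a synthetic cohort.

    Organisms are named org01..orgNN. ``clades`` maps clade name -> member
    ids; ``signatures`` maps clade name -> the repeat class enriched only in
    that clade; ``peaks`` maps organism id -> list of PeakPlan. Baseline
    classes are drawn from the 501 and shared by every organism, with
    per-organism abundance noise.
    """

    n_organisms: int
    genome_length: int = 120_000
    background_gc: float = 0.42
    subgroup_of: dict[str, str] = field(default_factory=dict)
    clades: dict[str, list[str]] = field(default_factory=dict)
    signatures: dict[str, str] = field(default_factory=dict)
    peaks: dict[str, list[PeakPlan]] = field(default_factory=dict)
    n_baseline_classes: int = 30
    signature_arrays: int = 40
    signature_array_bp: int = 45
    seed: int = 0


@dataclass
class SyntheticCohort:
    plan: CohortPlan
    genomes: dict[str, SyntheticGenome]

    @property
    def organism_ids(self) -> list[str]:
        return list(self.genomes)

    def subgroups(self) -> dict[str, str]:
        return {o: g.spec.subgroup for o, g in self.genomes.items()}


def _organism_ids(n: int) -> list[str]:
    return [f"org{i + 1:02d}" for i in range(n)]


def _actual_motif_for(repeat_class: str) -> str:
    return repeat_class  # plant arrays in canonical phase


def generate_cohort(plan: CohortPlan) -> SyntheticCohort:
    """Generate every organism of a cohort, deterministic given plan.seed."""
    rng = np.random.default_rng(plan.seed)
    ids = _organism_ids(plan.n_organisms)
    known = set(ids)
    for clade, members in plan.clades.items():
        if set(members) - known:
            raise ValueError(f"clade {clade} names unknown organisms")
    sig_classes = list(plan.signatures.values())
    if len(set(sig_classes)) != len(sig_classes):
        raise ValueError("signature class duplicated across clades")
    all_classes = class_order(6)
    reserved = set(sig_classes) | {
        p.repeat_class for plans in plan.peaks.values() for p in plans
    }
    pool = [c for c in all_classes if c not in reserved and len(c) >= 2]
    baseline = list(rng.choice(pool, size=plan.n_baseline_classes, replace=False))

    org_clade = {}
    for clade, members in plan.clades.items():
        for m in members:
            org_clade[m] = clade

    genomes: dict[str, SyntheticGenome] = {}
    for org in ids:
        org_seed = int(rng.integers(0, 2**31 - 1))
        org_rng = np.random.default_rng(org_seed)
        planted: list[PlantedRepeat] = []
        for cls in baseline:
            n_arrays = 1 + int(org_rng.poisson(5))
            for _ in range(n_arrays):
                length = int(org_rng.integers(12, 40))
                planted.append(PlantedRepeat(_actual_motif_for(cls), length))
        clade = org_clade.get(org)
        if clade is not None and clade in plan.signatures:
            cls = plan.signatures[clade]
            # jitter count and lengths so clade densities have nonzero
            # variance; lengths decay geometrically so the class's unit-length
            # histogram stays monotone (no incidental length-preference bump)
            n_sig = plan.signature_arrays + int(org_rng.integers(0, 6))
            k = len(cls)
            base_units = max(2, plan.signature_array_bp // k)
            for _ in range(n_sig):
                units = base_units + int(org_rng.geometric(0.6)) - 1
                length = max(DEFAULT_MIN_LENGTH, units * k)
                planted.append(PlantedRepeat(_actual_motif_for(cls), length))
        for pp in plan.peaks.get(org, []):
            k = len(pp.repeat_class)
            for units, count in pp.histogram.items():
                if units * k < DEFAULT_MIN_LENGTH:
                    raise ValueError(
                        f"peak plan for {pp.repeat_class} includes arrays below "
                        f"the detection cutoff (unit length {units})"
                    )
                for _ in range(count):
                    planted.append(
                        PlantedRepeat(_actual_motif_for(pp.repeat_class), units * k)
                    )
        spec = SyntheticGenomeSpec(
            organism_id=org,
            genome_length=plan.genome_length,
            background_gc=plan.background_gc,
            rng_seed=org_seed,
            planted=planted,
            subgroup=plan.subgroup_of.get(org, "sg1"),
        )
        genomes[org] = generate_genome(spec)
    return SyntheticCohort(plan=plan, genomes=genomes)


def simulate_cohort_stats(
    n_organisms: int,
    clades: Mapping[str, Sequence[str]] | None = None,
    signatures: Mapping[str, str] | None = None,
    signature_fold: float = 10.0,
    seed: int = 0,
    max_k: int = 6,
) -> pd.DataFrame:
    """Sample a cohort's per-class statistics directly (no sequences).

    Models the cross-genome structure the rank analyses assume: each class
    has a shared abundance scale (common repeats are common everywhere) with
    lognormal per-organism noise; about half the classes are rare. Clade
    signatures are planted by raising the class's density to
    ``signature_fold`` times the organism's 10th-highest baseline density in
    every clade member. Returns a long DataFrame (organism_id, repeat_class,
    frequency, bases, density).
    """
    rng = np.random.default_rng(seed)
    classes = class_order(max_k)
    ids = _organism_ids(n_organisms)
    clades = dict(clades or {})
    signatures = dict(signatures or {})
    sig_set = set(signatures.values())
    unknown = sig_set - set(classes)
    if unknown:
        raise ValueError(f"unknown signature classes {sorted(unknown)}")
    n_cls = len(classes)
    class_scale = np.exp(rng.normal(0.0, 2.0, size=n_cls))
    rare = rng.random(n_cls) < 0.5
    class_scale[rare] *= 0.01
    # keep signature classes rare at baseline so they are never top-10 by chance
    for cls in sig_set:
        class_scale[classes.index(cls)] = np.percentile(class_scale, 5)
    org_clade: dict[str, str] = {}
    for clade, members in clades.items():
        for m in members:
            org_clade[m] = clade
    rows = []
    for org in ids:
        noise = np.exp(rng.normal(0.0, 0.5, size=n_cls))
        density = class_scale * noise * 100.0
        clade = org_clade.get(org)
        if clade in signatures:
            top10 = np.sort(density)[-10]
            density[classes.index(signatures[clade])] = signature_fold * top10 * float(
                np.exp(rng.normal(0.0, 0.1))
            )
        frequency = np.round(density * 0.5).astype(int)
        bases = np.round(density * 30).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "organism_id": org,
                    "repeat_class": classes,
                    "frequency": frequency,
                    "bases": bases,
                    "density": density,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_cohort(cohort: SyntheticCohort, out_dir) -> pd.DataFrame:
    """Write FASTA/GFF/truth per organism plus a manifest TSV; returns the manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (org, genome) in enumerate(cohort.genomes.items()):
        fasta = out / f"{org}.fa"
        truth = out / f"{org}.truth.tsv"
        genome.write_fasta(fasta)
        genome.write_truth(truth)
        gff = ""
        if genome.spec.genes:
            gff_path = out / f"{org}.gff3"
            genome.write_gff(gff_path)
            gff = gff_path.name
        rows.append(
            {
                "organism_id": org,
                "fasta": fasta.name,
                "gff": gff,
                "group": "synthetic",
                "subgroup": genome.spec.subgroup,
                "order_index": i,
                "seed": genome.spec.rng_seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
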