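"""Perfect-SSR detection: worked examples, oracle agreement, invariants."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrscape.detect import (
    FastaError,
    SequenceAlphabetError,
    scan_fasta,
    scan_sequence,
    sequence_stats,
    write_bed,
)
from ssrscape.motifs import is_primitive

from .reference import ref_scan


def _tuples(records):
    return [(r.start, r.end, r.actual_motif) for r in records]


def test_single_dinucleotide_run():
    records = scan_sequence("x", "ACACACACACAC")
    assert len(records) == 1
    r = records[0]
    assert (r.start, r.end, r.repeat_class, r.units) == (0, 12, "AC", 6)


def test_below_cutoff_yields_nothing():
    assert scan_sequence("x", "AAAAAAAAAAA") == []


def test_agat_array():
    records = scan_sequence("x", "GATA" * 12)
    assert len(records) == 1
    r = records[0]
    assert (r.repeat_class, r.length_bp, r.units) == ("AGAT", 48, 12)
    assert r.actual_motif == "GATA"  # as read at the repeat's first base


def test_partial_trailing_unit_counts_toward_length():
    # 14 bp of AAAT: 3 complete units + 2 extra bases
    records = scan_sequence("x", "G" + "AAATAAATAAATAA" + "GG")
    assert len(records) == 1
    r = records[0]
    assert (r.start, r.end, r.length_bp, r.units, r.repeat_class) == (1, 15, 14, 3, "AAAT")


def test_soft_masked_sequence_is_scanned():
    records = scan_sequence("x", "acacacacacac")
    assert len(records) == 1
    assert records[0].repeat_class == "AC"


def test_n_breaks_runs():
    seq = "ACACACACACAC" + "N" + "ACACACACACAC"
    records = scan_sequence("x", seq)
    assert _tuples(records) == [(0, 12, "AC"), (13, 25, "AC")]


def test_ambiguity_codes_behave_like_n_and_invalid_chars_raise():
    seq = "ACACACACACAC" + "R" + "ACACACACACAC"
    assert len(scan_sequence("x", seq)) == 2
    with pytest.raises(SequenceAlphabetError):
        scan_sequence("x", "ACGT?ACGT")


def test_poly_a_never_reported_under_larger_motif():
    records = scan_sequence("x", "G" + "A" * 30 + "G")
    assert len(records) == 1
    assert records[0].repeat_class == "A"
    assert records[0].k == 1


@pytest.mark.parametrize("seed", range(12))
def test_matches_naive_oracle_on_random_sequences(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    got = _tuples(scan_sequence("s", seq))
    assert got == ref_scan(seq)


def test_matches_oracle_on_repeat_rich_sequence(rng):
    # stitch random fragments with planted arrays to exercise junctions
    parts = []
    for _ in range(60):
        parts.append("".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40)))))
        motif = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
        reps = int(rng.integers(2, 30))
        parts.append(motif * reps)
    seq = "".join(parts)
    assert _tuples(scan_sequence("s", seq)) == ref_scan(seq)


def test_emitted_records_are_perfect_primitive_and_maximal(rng):
    seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=30_000))
    records = scan_sequence("s", seq)
    assert records, "AT-rich sequence should contain repeats"
    prev_end = -1
    for r in records:
        assert r.start >= prev_end  # non-overlapping, sorted
        prev_end = r.end
        slice_ = seq[r.start : r.end]
        expanded = (r.actual_motif * (r.length_bp // r.k + 1))[: r.length_bp]
        assert slice_ == expanded  # perfect-slice property
        assert is_primitive(r.actual_motif)
        # right-maximality: one more base would break the period
        if r.end < len(seq):
            assert seq[r.end] != seq[r.end - r.k]
        # left-maximality, unless the previous record claimed that base
        if r.start > 0 and not any(q.end == r.start for q in records):
            assert seq[r.start - 1] != seq[r.start - 1 + r.k]


def test_concatenation_safety(rng):
    contigs = [
        "".join(rng.choice(list("ACGT"), p=[0.35, 0.15, 0.15, 0.35], size=4000))
        for _ in range(4)
    ]
    separate = []
    for c in contigs:
        separate.extend(_tuples(scan_sequence("s", c)))
    joined = scan_sequence("s", "N".join(contigs))
    offsets = []
    pos = 0
    for c in contigs:
        offsets.append(pos)
        pos += len(c) + 1
    rebased = []
    for r in joined:
        off = max(o for o in offsets if o <= r.start)
        rebased.append((r.start - off, r.end - off, r.actual_motif))
    assert rebased == separate


@given(st.text("ACGTN", min_size=0, max_size=120))
@settings(max_examples=150, deadline=None)
def test_oracle_agreement_property(seq):
    assert _tuples(scan_sequence("s", seq)) == ref_scan(seq)


def test_scan_fasta_planted_and_stats(tmp_path, small_genome):
    fasta = tmp_path / "g.fa"
    small_genome.write_fasta(fasta)
    records, stats = scan_fasta(fasta)
    truth = small_genome.expected_records()
    assert sorted(records, key=lambda r: r.start) == sorted(truth, key=lambda r: r.start)
    assert stats[0].length_bp == small_genome.spec.genome_length


def test_scan_fasta_gzip_and_two_contigs(tmp_path):
    fasta = tmp_path / "two.fa.gz"
    with gzip.open(fasta, "wt") as out:
        out.write(">c1\nGGGTTTGGGTTTAAC\n>c2\nTT" + "AC" * 10 + "TT\n")
    records, stats = scan_fasta(fasta)
    assert [(r.seq_id, r.start, r.end) for r in records] == [
        ("c1", 0, 12),
        ("c2", 2, 22),
    ]
    assert [s.seq_id for s in stats] == ["c1", "c2"]


def test_scan_fasta_all_n_contig(tmp_path):
    fasta = tmp_path / "n.fa"
    fasta.write_text(">c1\n" + "N" * 100 + "\n")
    records, stats = scan_fasta(fasta)
    assert records == []
    assert stats[0].length_bp == 100
    assert stats[0].n_count == 100


def test_scan_fasta_errors(tmp_path):
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(FastaError):
        scan_fasta(empty)
    dup = tmp_path / "dup.fa"
    dup.write_text(">a\nACGT\n>a\nACGT\n")
    with pytest.raises(FastaError):
        scan_fasta(dup)


def test_sequence_stats_gc_over_non_n():
    s = sequence_stats("x", "GGCCNNNNAATT")
    assert s.length_bp == 12
    assert s.n_count == 4
    assert s.gc_fraction == pytest.approx(0.5)


def test_bed_roundtrip(tmp_path):
    records = scan_sequence("x", "TT" + "AC" * 10 + "G" + "AAAT" * 4)
    path = tmp_path / "out.bed"
    write_bed(records, path)
    lines = path.read_text().strip().split("\n")
    assert lines[0].startswith("#seq_id\tstart\tend")
    fields = lines[1].split("\t")
    assert fields[:4] == ["x", "2", "22", "AC"]
    assert fields[5] == "+"
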