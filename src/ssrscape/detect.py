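"""Exhaustive detection of perfect microsatellites in genome sequences.

Scans each sequence for maximal perfect tandem repeats of primitive 1-6 nt
motifs whose total length (including a partial trailing unit) reaches a
configurable cutoff, 12 bp by default — i.e. at least two complete units of
the largest motif size. Coordinates follow the BED convention (0-based,
half-open). Runs are broken by N characters and sequence ends; soft-masked
(lowercase) sequence is scanned like unmasked sequence.

Overlap resolution is left-to-right greedy: at each position the longest
maximal perfect run starting there is taken (ties between motif sizes go to
the smaller motif), emitted if long enough, and scanning resumes at its end.
This makes output deterministic and guarantees every emitted motif is
primitive (a run explained by a shorter period is always claimed by the
smaller motif size first).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .motifs import canonical_class

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 12
DEFAULT_MAX_K = 6

# Byte codes for unambiguous bases; everything ambiguous is mapped to 0 and
# behaves like N (matches nothing, not even itself).
_BASE_CODES = {base: ord(base) for base in "ACGT"}
_AMBIGUOUS = set(b"NRYSWKMBDHV")

_DECODE_TABLE = np.zeros(256, dtype=np.uint8)
for _b, _c in _BASE_CODES.items():
    _DECODE_TABLE[ord(_b)] = _c
    _DECODE_TABLE[ord(_b.lower())] = _c
_VALID = np.zeros(256, dtype=bool)
for _b in "ACGT":
    _VALID[ord(_b)] = _VALID[ord(_b.lower())] = True
for _b in _AMBIGUOUS:
    _VALID[_b] = True
    _VALID[ord(chr(_b).lower())] = True


class SequenceAlphabetError(ValueError):
    """Sequence contains characters outside ACGTN / IUPAC ambiguity codes."""


class FastaError(ValueError):
    """Malformed FASTA input (empty file, duplicate ids)."""


@dataclass(frozen=True)
class SSRRecord:
    """One detected perfect SSR.

    ``actual_motif`` is the motif as read at the repeat's first base;
    ``repeat_class`` is its canonical class. ``length_bp`` counts partial
    trailing units; ``units`` counts only complete motif copies.
    """

    seq_id: str
    start: int
    end: int
    repeat_class: str
    actual_motif: str
    k: int
    length_bp: int
    units: int


@dataclass(frozen=True)
class SequenceStats:
    """Per-sequence bookkeeping: length, GC of non-N bases, N count."""

    seq_id: str
    length_bp: int
    gc_fraction: float
    n_count: int


def _encode(sequence: str, seq_id: str) -> np.ndarray:
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    invalid = ~_VALID[raw]
    if invalid.any():
        bad = chr(raw[np.argmax(invalid)])
        raise SequenceAlphabetError(
            f"sequence {seq_id!r} contains invalid character {bad!r}"
        )
    encoded = _DECODE_TABLE[raw]
    n_like = int((encoded == 0).sum())
    n_literal = int(np.isin(raw, (ord("N"), ord("n"))).sum())
    if n_like > n_literal:
        logger.info(
            "sequence %s: %d non-N ambiguity bases treated as N",
            seq_id,
            n_like - n_literal,
        )
    return encoded


def _run_lengths(eq: np.ndarray) -> np.ndarray:
    """For each index i, the length of the run of True starting at i."""
    n = len(eq)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    false_pos = np.flatnonzero(~eq)
    boundaries = np.append(false_pos, n)
    nxt = boundaries[np.searchsorted(boundaries, np.arange(n))]
    return nxt - np.arange(n)


def _extension_table(encoded: np.ndarray, max_k: int) -> tuple[np.ndarray, np.ndarray]:
    """Best run length and motif size for a run starting at each position.

    best_len[i] = max over k of the maximal perfect-run length with period k
    starting at i (k + number of following positions matching k bases back);
    best_k[i] is the smallest k achieving it.
    """
    n = len(encoded)
    positions = np.arange(n, dtype=np.int64)
    best_len = np.zeros(n, dtype=np.int64)
    best_k = np.zeros(n, dtype=np.int64)
    for k in range(1, max_k + 1):
        if n < k:
            break
        a, b = encoded[k:], encoded[:-k] if k else encoded
        eq = (a == b) & (a != 0) & (b != 0)
        lengths = np.zeros(n, dtype=np.int64)
        lengths[: n - k] = k + _run_lengths(eq)
        lengths[n - k :] = n - positions[n - k :]
        np.minimum(lengths, n - positions, out=lengths)
        better = lengths > best_len
        best_len[better] = lengths[better]
        best_k[better] = k
    return best_len, best_k


def scan_sequence(
    seq_id: str,
    sequence: str,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_k: int = DEFAULT_MAX_K,
) -> list[SSRRecord]:
    """Find all perfect SSRs of motif size 1..max_k and length >= min_length.

    Returns non-overlapping, maximal records sorted by start. With
    min_length < 2*max_k a reported run may hold fewer than two full units
    of its motif; the default 12 bp cutoff guarantees at least two complete
    hexamer units.
    """
    if min_length < 2:
        raise ValueError(f"min_length must be >= 2, got {min_length}")
    if not 1 <= max_k <= 6:
        raise ValueError(f"max_k must be in 1..6, got {max_k}")
    encoded = _encode(sequence, seq_id)
    n = len(encoded)
    if n < min_length:
        return []
    best_len, best_k = _extension_table(encoded, max_k)
    upper = sequence.upper()
    records: list[SSRRecord] = []
    i = 0
    while i <= n - min_length:
        length = int(best_len[i])
        if length >= min_length:
            k = int(best_k[i])
            motif = upper[i : i + k]
            if "N" not in motif:  # only possible when min_length < 2*max_k
                records.append(
                    SSRRecord(
                        seq_id=seq_id,
                        start=i,
                        end=i + length,
                        repeat_class=canonical_class(motif),
                        actual_motif=motif,
                        k=k,
                        length_bp=length,
                        units=length // k,
                    )
                )
                i += length
                continue
        i += 1
    return records


def sequence_stats(seq_id: str, sequence: str) -> SequenceStats:
    """Length, non-N GC fraction, and N count of one sequence."""
    encoded = _encode(sequence, seq_id)
    n_count = int((encoded == 0).sum())
    informative = len(encoded) - n_count
    gc = int(np.isin(encoded, (ord("G"), ord("C"))).sum())
    return SequenceStats(
        seq_id=seq_id,
        length_bp=len(encoded),
        gc_fraction=gc / informative if informative else 0.0,
        n_count=n_count,
    )


def _open_fasta(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (seq_id, sequence) pairs from a plain or gzipped FASTA file."""
    seen: set[str] = set()
    empty = True
    with _open_fasta(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            empty = False
            if rec.id in seen:
                raise FastaError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            yield rec.id, str(rec.seq)
    if empty:
        raise FastaError(f"no FASTA records in {path}")


def scan_fasta(
    path,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_k: int = DEFAULT_MAX_K,
) -> tuple[list[SSRRecord], list[SequenceStats]]:
    """Scan every sequence of a FASTA file.

    Sequences are processed one at a time, so peak memory tracks the longest
    contig rather than the assembly.
    """
    records: list[SSRRecord] = []
    stats: list[SequenceStats] = []
    for seq_id, sequence in iter_fasta(path):
        records.extend(scan_sequence(seq_id, sequence, min_length, max_k))
        stats.append(sequence_stats(seq_id, sequence))
    return records, stats


BED_COLUMNS = (
    "seq_id",
    "start",
    "end",
    "repeat_class",
    "length_bp",
    "strand",
    "actual_motif",
    "units",
)


def write_bed(records: Iterable[SSRRecord], path) -> None:
    """Write records as BED6+ TSV (strand is always '+': classes are strand-collapsed)."""
    with open(path, "w") as out:
        out.write("#" + "\t".join(BED_COLUMNS) + "\n")
        for r in records:
            out.write(
                f"{r.seq_id}\t{r.start}\t{r.end}\t{r.repeat_class}\t"
                f"{r.length_bp}\t+\t{r.actual_motif}\t{r.units}\n"
            )
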