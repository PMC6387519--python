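"""Motif algebra for microsatellite repeat classes.

A microsatellite (SSR) motif is a short DNA word of 1-6 nt. Because a tandem
array can be read starting at any phase and on either strand, motifs that are
cyclic rotations of each other, or of each other's reverse complement, describe
the same repeat. This module enumerates the *primitive* motifs (those not
themselves a tandem repetition of a shorter word) and collapses them into
canonical *repeat classes*: the lexicographically smallest rotation over the
motif and its reverse complement. For motif sizes 1-6 there are 5356 primitive
motifs forming 501 repeat classes.

Classes are further categorized by motif size (monomer..hexamer) and by the GC
content of the 12 bp string obtained by repeating the canonical motif in tandem
(12 bp being the minimum repeat length used throughout the pipeline). The 12 bp
window matters for pentamers, where the third unit is truncated and the window
GC can differ from the motif's own GC.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass

import pandas as pd

ALPHABET = "ACGT"
MAX_MOTIF_SIZE = 6
GC_WINDOW = 12

#: GC-category labels, in increasing GC order.
GC_CATEGORIES = ("LE25", "GC26_49", "GC50", "GC51_74", "GE75")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class MotifError(ValueError):
    """Invalid motif: wrong alphabet, empty, or out-of-range size."""


class NonPrimitiveMotifError(MotifError):
    """Motif is a tandem repetition of a shorter motif (e.g. ACAC = AC x 2)."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an ACGT string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _validate_alphabet(sequence: str) -> None:
    if not sequence:
        raise MotifError("empty motif")
    if any(base not in ALPHABET for base in sequence):
        raise MotifError(f"motif {sequence!r} contains non-ACGT characters")


def is_primitive(sequence: str) -> bool:
    """True iff ``sequence`` is not a shorter word repeated in tandem.

    "AC" is primitive; "ACAC" (= AC x 2) and "AAA" (= A x 3) are not.
    """
    _validate_alphabet(sequence)
    n = len(sequence)
    for d in range(1, n):
        if n % d == 0 and sequence[:d] * (n // d) == sequence:
            return False
    return True


def rotations(sequence: str) -> list[str]:
    """All cyclic rotations of a string (length k -> k strings)."""
    return [sequence[i:] + sequence[:i] for i in range(len(sequence))]


def canonical_class(motif: str) -> str:
    """Canonical repeat-class representative of a primitive motif.

    The representative is the lexicographically smallest string among all
    cyclic rotations of the motif and of its reverse complement, so every
    member of a class (any phase, either strand) maps to the same name:
    TTC -> AAG, ACGT -> ACGT, CTCGAG -> AGCTCG.

    Raises :class:`NonPrimitiveMotifError` for non-primitive input and
    :class:`MotifError` for non-ACGT characters.
    """
    if not is_primitive(motif):
        raise NonPrimitiveMotifError(f"motif {motif!r} is not primitive")
    return min(rotations(motif) + rotations(reverse_complement(motif)))


def enumerate_primitive_motifs(max_k: int = MAX_MOTIF_SIZE) -> list[str]:
    """All primitive motifs of size 1..max_k, sorted by (size, lexicographic).

    For max_k = 6 this yields the 5356 motif permutations underlying the
    501 repeat classes.
    """
    if not 1 <= max_k <= MAX_MOTIF_SIZE:
        raise MotifError(f"max_k must be in 1..{MAX_MOTIF_SIZE}, got {max_k}")
    motifs: list[str] = []
    for k in range(1, max_k + 1):
        motifs.extend(
            m
            for m in ("".join(p) for p in itertools.product(ALPHABET, repeat=k))
            if is_primitive(m)
        )
    return motifs


def tandem_expansion(motif: str, window: int = GC_WINDOW) -> str:
    """The first ``window`` bases of the motif repeated in tandem."""
    reps = -(-window // len(motif))
    return (motif * reps)[:window]


def gc_fraction_12bp(motif: str) -> float:
    """GC fraction of the 12 bp tandem expansion of a motif."""
    window = tandem_expansion(motif)
    return (window.count("G") + window.count("C")) / len(window)


def gc_category(motif_or_class: "str | RepeatClass") -> str:
    """Five-way GC category of a repeat class.

    Computed on the 12 bp tandem expansion; with a denominator of 12 the
    boundaries reduce to integer GC counts: <=3 -> LE25, 4-5 -> GC26_49,
    6 -> GC50, 7-8 -> GC51_74, >=9 -> GE75.
    """
    motif = (
        motif_or_class.canonical
        if isinstance(motif_or_class, RepeatClass)
        else motif_or_class
    )
    window = tandem_expansion(motif)
    gc = window.count("G") + window.count("C")
    if gc <= 3:
        return "LE25"
    if gc < 6:
        return "GC26_49"
    if gc == 6:
        return "GC50"
    if gc < 9:
        return "GC51_74"
    return "GE75"


@dataclass(frozen=True)
class RepeatClass:
    """One equivalence class of motifs under rotation and reverse complement.

    Attributes
    ----------
    canonical : str
        Class representative (lexicographic minimum of the orbit).
    k : int
        Motif size in nt (1..6).
    orbit_size : int
        Number of distinct primitive motifs mapping to this class.
    gc_fraction : float
        GC fraction of the 12 bp tandem expansion of the canonical motif.
    gc_category : str
        One of :data:`GC_CATEGORIES`.
    """

    canonical: str
    k: int
    orbit_size: int
    gc_fraction: float
    gc_category: str


@functools.lru_cache(maxsize=None)
def _enumerate_classes_cached(max_k: int) -> tuple[RepeatClass, ...]:
    orbits: dict[str, int] = {}
    for motif in enumerate_primitive_motifs(max_k):
        rep = canonical_class(motif)
        orbits[rep] = orbits.get(rep, 0) + 1
    classes = [
        RepeatClass(
            canonical=rep,
            k=len(rep),
            orbit_size=size,
            gc_fraction=gc_fraction_12bp(rep),
            gc_category=gc_category(rep),
        )
        for rep, size in orbits.items()
    ]
    classes.sort(key=lambda c: (c.k, c.canonical))
    return tuple(classes)


def enumerate_classes(max_k: int = MAX_MOTIF_SIZE) -> list[RepeatClass]:
    """All repeat classes for motif sizes 1..max_k.

    Order is stable (motif size ascending, then lexicographic) so downstream
    matrices always share a column order. max_k = 6 yields the 501 classes.
    """
    if not 1 <= max_k <= MAX_MOTIF_SIZE:
        raise MotifError(f"max_k must be in 1..{MAX_MOTIF_SIZE}, got {max_k}")
    return list(_enumerate_classes_cached(max_k))


def class_order(max_k: int = MAX_MOTIF_SIZE) -> list[str]:
    """Canonical motifs in the stable class order (column order everywhere)."""
    return [c.canonical for c in enumerate_classes(max_k)]


def class_table(max_k: int = MAX_MOTIF_SIZE) -> pd.DataFrame:
    """Repeat-class table as a DataFrame (canonical, k, orbit_size, gc_*)."""
    return pd.DataFrame(
        [
            {
                "canonical": c.canonical,
                "k": c.k,
                "orbit_size": c.orbit_size,
                "gc_fraction": c.gc_fraction,
                "gc_category": c.gc_category,
            }
            for c in enumerate_classes(max_k)
        ]
    )


def write_class_table(path, max_k: int = MAX_MOTIF_SIZE) -> None:
    """Export the class table as TSV."""
    class_table(max_k).to_csv(path, sep="\t", index=False)
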