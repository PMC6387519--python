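"""Repeat-length analytics: longest instances and length-preference peaks.

SSR abundance is expected to fall off monotonically with repeat length
(longer perfect repeats accumulate mutations). Two kinds of departure are
measured here: (i) the longest instances per organism and the per-class
medians of the longest instances, and (ii) *length preference* — a local
bump in the unit-length abundance histogram of a repeat class, detected by
scanning consecutive unit lengths for a rise to a local maximum that later
falls back below the abundance at the bump's start. Candidate bumps are kept
only if they span at least 4 consecutive unit lengths (start and end
included) and the abundance at the peak start exceeds 10.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detect import SSRRecord

MIN_PEAK_SPAN = 4
MIN_START_ABUNDANCE = 10


@dataclass(frozen=True)
class LengthPreferencePeak:
    """One detected abundance bump in a unit-length histogram."""

    repeat_class: str
    organism_id: str
    peak_start: int  # unit length just before the first rise
    maxima: int  # unit length of the highest abundance inside the bump
    end: int  # first unit length where abundance drops below the start's
    span: int  # end - peak_start + 1
    start_abundance: int


def top_n_longest(records: Sequence[SSRRecord], n: int = 100) -> list[SSRRecord]:
    """The n longest records by length_bp; ties broken by (seq_id, start)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(records, key=lambda r: (-r.length_bp, r.seq_id, r.start))
    return ordered[:n]


def class_length_medians(
    records: Sequence[SSRRecord], n: int = 1000
) -> pd.Series:
    """Median length of the up-to-n longest instances of each repeat class.

    Classes with no instances are absent from the result (reported missing).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    by_class: dict[str, list[int]] = {}
    for r in records:
        by_class.setdefault(r.repeat_class, []).append(r.length_bp)
    medians = {
        cls: float(pd.Series(sorted(lengths, reverse=True)[:n]).median())
        for cls, lengths in by_class.items()
    }
    return pd.Series(medians, name="median_length_bp").sort_index()


def unit_length_histogram(
    records: Iterable[SSRRecord], repeat_class: str
) -> dict[int, int]:
    """Abundance of one repeat class at each complete-unit length."""
    counts = Counter(
        r.units for r in records if r.repeat_class == repeat_class
    )
    return dict(sorted(counts.items()))


def detect_length_preference(
    counts: Mapping[int, int],
    repeat_class: str = "",
    organism_id: str = "",
    min_span: int = MIN_PEAK_SPAN,
    min_start_abundance: int = MIN_START_ABUNDANCE,
) -> list[LengthPreferencePeak]:
    """Scan a unit-length histogram for abundance bumps.

    Missing unit lengths inside the observed range count as abundance 0. The
    scan walks consecutive unit lengths; the unit before the first detected
    rise is the peak start; the bump must reach a local maximum and the
    endpoint is the first unit where abundance falls strictly below the
    start abundance. A candidate with no such endpoint before the histogram
    ends is discarded. After a bump (kept or filtered out), scanning resumes
    at its endpoint, so disjoint bumps are all reported.
    """
    observed = [u for u, c in counts.items() if c > 0]
    if not observed:
        return []
    # zero-count entries outside the observed range carry no information and
    # must not manufacture endpoints for otherwise-unterminated bumps
    lo, hi = min(observed), max(observed)
    units = list(range(lo, hi + 1))
    a = [int(counts.get(u, 0)) for u in units]
    peaks: list[LengthPreferencePeak] = []
    i = 0
    while i < len(a) - 1:
        if a[i + 1] > a[i]:  # rise detected; a plateau is not a rise
            start = i
            end = None
            for j in range(i + 1, len(a)):
                if a[j] < a[start]:
                    end = j
                    break
            if end is None:
                # abundance never falls back below the start: no endpoint,
                # candidate discarded
                i += 1
                continue
            inner = range(start + 1, end)
            maxima = max(inner, key=lambda j: (a[j], -j))
            span = units[end] - units[start] + 1
            if span >= min_span and a[start] > min_start_abundance:
                peaks.append(
                    LengthPreferencePeak(
                        repeat_class=repeat_class,
                        organism_id=organism_id,
                        peak_start=units[start],
                        maxima=units[maxima],
                        end=units[end],
                        span=span,
                        start_abundance=a[start],
                    )
                )
            i = end + 1  # scanning resumes just past the bump's endpoint
        else:
            i += 1
    return peaks


def cohort_peaks(
    records_by_organism: Mapping[str, Sequence[SSRRecord]],
    min_span: int = MIN_PEAK_SPAN,
    min_start_abundance: int = MIN_START_ABUNDANCE,
) -> pd.DataFrame:
    """Length-preference peaks for every (organism, class) with any records."""
    rows = []
    for organism_id, records in records_by_organism.items():
        classes = sorted({r.repeat_class for r in records})
        for cls in classes:
            hist = unit_length_histogram(records, cls)
            for p in detect_length_preference(
                hist, cls, organism_id, min_span, min_start_abundance
            ):
                rows.append(
                    {
                        "organism_id": p.organism_id,
                        "repeat_class": p.repeat_class,
                        "peak_start": p.peak_start,
                        "maxima": p.maxima,
                        "end": p.end,
                        "span": p.span,
                        "start_abundance": p.start_abundance,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "organism_id",
            "repeat_class",
            "peak_start",
            "maxima",
            "end",
            "span",
            "start_abundance",
        ],
    )


def preference_prevalence(
    peaks: pd.DataFrame,
    organism_subgroup: Mapping[str, str],
) -> pd.DataFrame:
    """Percent of organisms per subgroup with a length preference per class.

    An organism counts once per class however many peaks it has. Values are
    percentages in [0, 100]; subgroups with no peak for a class read 0.
    """
    unknown = set(peaks["organism_id"]) - set(organism_subgroup)
    if unknown:
        raise ValueError(f"unknown organisms in peaks table: {sorted(unknown)}")
    subgroup_sizes = Counter(organism_subgroup.values())
    classes = sorted(set(peaks["repeat_class"]))
    subgroups = sorted(subgroup_sizes)
    table = pd.DataFrame(0.0, index=subgroups, columns=classes)
    seen = peaks[["organism_id", "repeat_class"]].drop_duplicates()
    for _, row in seen.iterrows():
        sg = organism_subgroup[row["organism_id"]]
        table.loc[sg, row["repeat_class"]] += 100.0 / subgroup_sizes[sg]
    return table
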