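"""Longest-instance analytics and length-preference peak detection."""

import numpy as np
import pytest

from ssrscape.detect import SSRRecord, scan_sequence
from ssrscape.lengths import (
    class_length_medians,
    cohort_peaks,
    detect_length_preference,
    preference_prevalence,
    top_n_longest,
    unit_length_histogram,
)


def _rec(length, cls="AC", seq_id="c1", start=0):
    k = len(cls)
    return SSRRecord(
        seq_id=seq_id,
        start=start,
        end=start + length,
        repeat_class=cls,
        actual_motif=cls,
        k=k,
        length_bp=length,
        units=length // k,
    )


def test_top_n_longest_returns_all_when_few():
    records = [_rec(20, start=i * 100) for i in range(5)]
    assert len(top_n_longest(records, 100)) == 5


def test_longest_planted_array_ranks_first():
    records = [_rec(52_000, cls="AAAT", start=100_000)] + [
        _rec(int(L), start=i * 100) for i, L in enumerate(np.linspace(12, 400, 50))
    ]
    top = top_n_longest(records, 100)
    assert top[0].repeat_class == "AAAT"
    assert top[0].length_bp == 52_000


def test_equal_lengths_ordered_by_position():
    records = [
        _rec(20, seq_id="c2", start=5),
        _rec(20, seq_id="c1", start=50),
        _rec(20, seq_id="c1", start=5),
    ]
    top = top_n_longest(records, 3)
    assert [(r.seq_id, r.start) for r in top] == [("c1", 5), ("c1", 50), ("c2", 5)]


def test_class_length_medians():
    records = [_rec(12), _rec(14, start=100), _rec(16, start=200)]
    medians = class_length_medians(records)
    assert medians["AC"] == 14
    assert "AT" not in medians.index  # absent class reported missing


def test_class_length_medians_honours_top_n():
    records = [_rec(L, start=i * 50) for i, L in enumerate([12, 14, 100, 102, 104])]
    medians = class_length_medians(records, n=3)
    assert medians["AC"] == 102  # median of the 3 longest only


def test_length_ordering_preserved_between_classes():
    at = [_rec(L, cls="AT", start=i * 2000) for i, L in enumerate(range(800, 1300, 50))]
    rare = [_rec(12, cls="AGCGCT", start=100_000 + i * 50) for i in range(5)]
    medians = class_length_medians(at + rare)
    assert medians["AT"] > medians["AGCGCT"]


def test_monotone_decreasing_histogram_has_no_peaks():
    assert detect_length_preference({2: 100, 3: 60, 4: 30, 5: 12, 6: 5}) == []


def test_worked_histogram_peak():
    peaks = detect_length_preference({2: 500, 3: 100, 4: 40, 5: 60, 6: 90, 7: 30, 8: 10})
    assert len(peaks) == 1
    p = peaks[0]
    assert (p.peak_start, p.maxima, p.end) == (4, 6, 7)
    assert p.span == 4
    assert p.start_abundance == 40


def test_low_start_abundance_is_filtered():
    assert detect_length_preference({2: 8, 3: 4, 4: 6, 5: 9, 6: 3}) == []


def test_narrow_bump_is_filtered():
    # rise at 4->5, fall below start at 6: span 3 < 4
    assert detect_length_preference({2: 500, 3: 100, 4: 40, 5: 90, 6: 10, 7: 5}) == []


def test_unterminated_bump_is_discarded():
    # abundance never falls back below the start abundance
    assert detect_length_preference({2: 500, 3: 40, 4: 60, 5: 90, 6: 80, 7: 70}) == []


def test_plateau_is_not_a_rise():
    assert detect_length_preference({2: 100, 3: 50, 4: 50, 5: 50, 6: 20}) == []


def test_multiple_disjoint_peaks():
    counts = {2: 500, 3: 100, 4: 40, 5: 60, 6: 90, 7: 30,
              8: 35, 9: 60, 10: 80, 11: 20, 12: 5}
    peaks = detect_length_preference(counts)
    assert [(p.peak_start, p.end) for p in peaks] == [(4, 7), (8, 11)]


def test_peaks_invariant_to_zero_padding():
    base = {2: 500, 3: 100, 4: 40, 5: 60, 6: 90, 7: 30, 8: 10}
    padded = dict(base)
    padded.update({u: 0 for u in range(9, 30)})
    assert detect_length_preference(base) == detect_length_preference(padded)
    # padding must not rescue an unterminated bump either
    bump = {2: 500, 3: 40, 4: 60, 5: 90, 6: 80, 7: 70}
    padded_bump = dict(bump)
    padded_bump.update({u: 0 for u in range(8, 15)})
    assert detect_length_preference(padded_bump) == []


@pytest.mark.parametrize("seed", range(10))
def test_planted_bump_recovery(seed):
    """A tall bump on a geometric baseline is found; weak/narrow bumps never are."""
    rng = np.random.default_rng(seed)
    units = np.arange(2, 25)
    baseline = np.maximum((4000 * 0.55 ** (units - 2)), 0).astype(int)
    counts = {int(u): int(c) for u, c in zip(units, baseline)}
    a, w, h = 10, 5, 400
    bumped = dict(counts)
    for u in range(a + 1, a + w):
        bumped[u] = counts.get(u, 0) + h + int(rng.integers(0, 20))
    peaks = detect_length_preference(bumped)
    assert any(p.peak_start == a for p in peaks)
    # same bump but squeezed below the span filter
    narrow = dict(counts)
    narrow[a + 1] = counts.get(a, 1) * 3
    assert all(p.peak_start != a for p in detect_length_preference(narrow))


def test_unit_length_histogram_counts_complete_units():
    seq = "G" + "AAAT" * 5 + "GG" + "AAAT" * 5 + "TT" + "ACACACACACAC"
    records = scan_sequence("x", seq)
    hist = unit_length_histogram(records, "AAAT")
    assert hist == {5: 2}


def test_cohort_peaks_and_prevalence():
    counts = {2: 500, 3: 100, 4: 40, 5: 60, 6: 90, 7: 30, 8: 10}
    records = []
    pos = 0
    for units, c in counts.items():
        for _ in range(c):
            records.append(_rec(units * 6, cls="AACCCT", start=pos))
            pos += units * 6 + 10
    peaks = cohort_peaks({"o1": records, "o2": []})
    assert len(peaks) == 1
    subgroups = {"o1": "mammals", "o2": "mammals", "o3": "birds"}
    prev = preference_prevalence(peaks, subgroups)
    assert prev.loc["mammals", "AACCCT"] == pytest.approx(50.0)
    assert prev.loc["birds", "AACCCT"] == 0.0
    with pytest.raises(ValueError):
        preference_prevalence(peaks, {"o9": "x"})


def test_prevalence_counts_organism_once_per_class():
    import pandas as pd

    peaks = pd.DataFrame(
        {
            "organism_id": ["o1", "o1"],
            "repeat_class": ["AGAT", "AGAT"],
            "peak_start": [4, 9],
            "maxima": [5, 10],
            "end": [7, 12],
            "span": [4, 4],
            "start_abundance": [20, 15],
        }
    )
    prev = preference_prevalence(peaks, {"o1": "m", "o2": "m"})
    assert prev.loc["m", "AGAT"] == pytest.approx(50.0)
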