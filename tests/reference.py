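"""Slow, independent reference implementations used as test oracles.

Everything here is deliberately written with plain string/list operations and
no imports from the package's internals, so agreement with the package is
evidence rather than tautology.
"""

from __future__ import annotations

import itertools

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def ref_revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def ref_is_primitive(s: str) -> bool:
    return not any(
        len(s) % d == 0 and s == s[:d] * (len(s) // d) for d in range(1, len(s))
    )


def ref_orbit(motif: str) -> set[str]:
    """All strings equivalent to motif under rotation and reverse complement."""
    rc = ref_revcomp(motif)
    out = set()
    for base in (motif, rc):
        for i in range(len(base)):
            out.add(base[i:] + base[:i])
    return out


def ref_classes(k: int) -> dict[str, set[str]]:
    """Group all primitive k-mers into orbits; canonical -> member set."""
    groups: dict[str, set[str]] = {}
    for tup in itertools.product("ACGT", repeat=k):
        s = "".join(tup)
        if not ref_is_primitive(s):
            continue
        orbit = {m for m in ref_orbit(s) if ref_is_primitive(m)}
        groups[min(orbit)] = orbit
    return groups


def ref_scan(seq: str, min_length: int = 12, max_k: int = 6):
    """Greedy maximal-perfect-run finder, naive char-by-char extension.

    Same resolution rule as the package scanner (longest run starting at each
    position, ties to the smaller motif size, skip to run end after emitting)
    but implemented with plain string indexing. N and other ambiguity codes
    never match anything. Returns (start, end, motif) tuples.
    """
    seq = seq.upper()
    seq = "".join(c if c in "ACGT" else "N" for c in seq)
    n = len(seq)
    out = []
    i = 0
    while i <= n - min_length:
        best_len, best_k = 0, 0
        for k in range(1, max_k + 1):
            if i + k > n:
                break
            j = i + k
            while j < n and seq[j] != "N" and seq[j] == seq[j - k]:
                j += 1
            length = j - i
            if length > best_len:
                best_len, best_k = length, k
        motif = seq[i : i + best_k]
        if best_len >= min_length and "N" not in motif:
            out.append((i, i + best_len, motif))
            i += best_len
        else:
            i += 1
    return out


def ref_average_linkage(points):
    """O(n^3) agglomerative average-linkage clustering, scipy-format linkage.

    ``points`` is a list of equal-length vectors. Ties in minimum distance are
    broken toward the lowest cluster-index pair, matching scipy's behaviour on
    distinct distances (tests only feed matrices with distinct merge
    distances).
    """
    import math

    n = len(points)
    clusters = {i: [i] for i in range(n)}
    centers = {i: list(points[i]) for i in range(n)}

    def dist(a, b):
        # average pairwise Euclidean distance between members
        total, count = 0.0, 0
        for i in clusters[a]:
            for j in clusters[b]:
                total += math.sqrt(
                    sum((x - y) ** 2 for x, y in zip(points[i], points[j]))
                )
                count += 1
        return total / count

    linkage = []
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                d = dist(keys[ai], keys[bi])
                if best is None or d < best[0]:
                    best = (d, keys[ai], keys[bi])
        d, a, b = best
        linkage.append((a, b, d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return linkage


def ref_leaf_order(linkage, n):
    """Left-to-right leaf order of a scipy-format linkage (recursive descent)."""

    def walk(node):
        if node < n:
            return [node]
        a, b, _, _ = linkage[node - n]
        return walk(int(a)) + walk(int(b))

    return walk(n + len(linkage) - 1)
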