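"""Rank-based enrichment scoring of repeat classes across organisms.

Within each organism the repeat classes are ranked by density (rank 1 =
densest; ties broken by frequency, then by class name) and mapped to a
six-level integer score:

* 3  — top 10 ranks
* 2  — ranks 11-25
* 1  — ranks 26-100
* 0  — middle ranks
* -1 — bottom 100 ranks with frequency >= 10
* -2 — frequency < 10, regardless of rank (guards against sampling noise)

Stacking the score vectors over organisms (rows, in evolutionary order)
against the stable class order (columns) gives the enrichment heat-map
matrix. Classes are then hierarchically clustered on the Euclidean distance
between score columns, and clade-specific signatures ("uniquely abundant"
classes: top-10 in every clade member and in no outsider) are validated with
a two-sample Welch t-test on the underlying densities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

SCORE_TOP10 = 3
SCORE_TOP25 = 2
SCORE_TOP100 = 1
SCORE_MID = 0
SCORE_BOTTOM100 = -1
SCORE_RARE = -2  # frequency < 10

LOW_FREQUENCY_CUTOFF = 10
TOP_ABUNDANT_RANK = 10


@dataclass(frozen=True)
class ScoreMatrix:
    """Organisms x classes integer score matrix (entries in -2..3)."""

    scores: pd.DataFrame  # index: organism ids, columns: canonical motifs

    @property
    def organisms(self) -> list[str]:
        return list(self.scores.index)

    @property
    def classes(self) -> list[str]:
        return list(self.scores.columns)


@dataclass(frozen=True)
class SignatureResult:
    repeat_class: str
    clade_ids: tuple[str, ...]
    uniquely_abundant: bool
    t_statistic: float | None
    p_value: float | None


def rank_classes(class_stats: pd.DataFrame) -> pd.Series:
    """Dense 1..n ranking of one organism's classes by density.

    Ties broken by frequency (descending) then canonical motif
    (lexicographic), so the ranking is a deterministic permutation.
    """
    df = class_stats.sort_values(
        ["density", "frequency", "repeat_class"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return pd.Series(
        np.arange(1, len(df) + 1), index=df["repeat_class"].to_numpy(), name="rank"
    )


def score_organism(class_stats: pd.DataFrame) -> pd.Series:
    """Score vector for one organism (index: repeat_class, stable order).

    ``class_stats`` is one organism's per-class table (repeat_class,
    frequency, density), one row per class.
    """
    n = len(class_stats)
    ranks = rank_classes(class_stats)
    order = class_stats["repeat_class"].to_numpy()
    freq = class_stats.set_index("repeat_class")["frequency"]
    bottom_cutoff = n - 100 + 1  # bottom 100 ranks of the full ranking
    scores = {}
    for cls in order:
        r = ranks[cls]
        if freq[cls] < LOW_FREQUENCY_CUTOFF:
            s = SCORE_RARE
        elif r <= 10:
            s = SCORE_TOP10
        elif r <= 25:
            s = SCORE_TOP25
        elif r <= 100:
            s = SCORE_TOP100
        elif r >= bottom_cutoff:
            s = SCORE_BOTTOM100
        else:
            s = SCORE_MID
        scores[cls] = s
    return pd.Series(scores, name="score").reindex(order).astype(int)


def build_score_matrix(
    cohort_stats: pd.DataFrame,
    organism_order: Sequence[str] | None = None,
) -> ScoreMatrix:
    """Score matrix from a long per-class table over a cohort.

    ``cohort_stats`` has columns organism_id, repeat_class, frequency,
    density. Rows of the matrix follow ``organism_order`` (default: order of
    first appearance, i.e. the supplied evolutionary order).
    """
    if organism_order is None:
        organism_order = list(dict.fromkeys(cohort_stats["organism_id"]))
    if len(set(organism_order)) != len(organism_order):
        raise ValueError("duplicate organism ids")
    rows = {}
    for org in organism_order:
        sub = cohort_stats[cohort_stats["organism_id"] == org]
        if sub.empty:
            raise ValueError(f"no class stats for organism {org!r}")
        rows[org] = score_organism(sub)
    matrix = pd.DataFrame(rows).T.loc[list(organism_order)]
    return ScoreMatrix(scores=matrix)


def cluster_classes(
    matrix: ScoreMatrix, method: str = "average"
) -> tuple[list[str], np.ndarray]:
    """Order classes by hierarchical clustering of score columns.

    Euclidean distance between columns; linkage method configurable (display
    order only — scores are never altered). Returns the leaf-ordered class
    list and the linkage array.
    """
    cols = matrix.scores.to_numpy().T.astype(float)
    if cols.shape[0] < 2:
        raise ValueError("need at least 2 classes to cluster")
    linkage = hierarchy.linkage(cols, method=method, metric="euclidean")
    order = hierarchy.leaves_list(linkage)
    return [matrix.classes[i] for i in order], linkage


def signature_test(
    repeat_class: str,
    clade_ids: Sequence[str],
    cohort_stats: pd.DataFrame,
) -> SignatureResult:
    """Is ``repeat_class`` uniquely abundant in ``clade_ids``?

    Uniquely abundant = within the top 10 density ranks in *every* clade
    member and in *no* organism outside the clade. Significance is a
    two-sided Welch t-test of the class's densities, clade vs all other
    organisms. Degenerate (zero-variance, equal) inputs report a missing p.
    """
    organisms = list(dict.fromkeys(cohort_stats["organism_id"]))
    clade = list(dict.fromkeys(clade_ids))
    unknown = set(clade) - set(organisms)
    if unknown:
        raise ValueError(f"unknown clade organisms {sorted(unknown)}")
    outside = [o for o in organisms if o not in set(clade)]
    if not clade or len(outside) < 2:
        raise ValueError(
            "clade must be a proper nonempty subset leaving >= 2 organisms outside"
        )
    in_top10 = {}
    densities = {}
    for org in organisms:
        sub = cohort_stats[cohort_stats["organism_id"] == org]
        ranks = rank_classes(sub)
        if repeat_class not in ranks.index:
            raise ValueError(f"class {repeat_class!r} missing for organism {org!r}")
        in_top10[org] = ranks[repeat_class] <= TOP_ABUNDANT_RANK
        densities[org] = float(
            sub.loc[sub["repeat_class"] == repeat_class, "density"].iloc[0]
        )
    unique = all(in_top10[o] for o in clade) and not any(in_top10[o] for o in outside)
    x = np.array([densities[o] for o in clade], float)
    y = np.array([densities[o] for o in outside], float)
    if (x.std(ddof=0) == 0 and y.std(ddof=0) == 0) or len(x) < 2:
        t_stat, p = None, None
    else:
        t_stat, p = sps.ttest_ind(x, y, equal_var=False)
        t_stat, p = float(t_stat), float(p)
        if math.isnan(p):
            t_stat, p = None, None
    return SignatureResult(
        repeat_class=repeat_class,
        clade_ids=tuple(clade),
        uniquely_abundant=bool(unique),
        t_statistic=t_stat,
        p_value=p,
    )


def scan_signatures(
    cohort_stats: pd.DataFrame,
    clades: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Test every (clade, class) pair where the class is top-10 in all members.

    Returns a table with class, clade, uniquely_abundant, t, p, p_adjusted,
    significant. The Bonferroni correction divides alpha by the number of
    uniquely-abundant candidates actually tested.
    """
    organisms = list(dict.fromkeys(cohort_stats["organism_id"]))
    ranks = {
        org: rank_classes(cohort_stats[cohort_stats["organism_id"] == org])
        for org in organisms
    }
    rows = []
    for clade_name, members in clades.items():
        members = list(members)
        outside = [o for o in organisms if o not in set(members)]
        if not members or len(outside) < 2:
            continue
        top10_all = set.intersection(
            *(set(ranks[o].index[ranks[o] <= TOP_ABUNDANT_RANK]) for o in members)
        )
        for cls in sorted(top10_all):
            res = signature_test(cls, members, cohort_stats)
            rows.append(
                {
                    "clade": clade_name,
                    "repeat_class": cls,
                    "uniquely_abundant": res.uniquely_abundant,
                    "t_statistic": res.t_statistic,
                    "p_value": res.p_value,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["clade", "repeat_class", "uniquely_abundant", "t_statistic", "p_value"],
    )
    n_tests = int(table["uniquely_abundant"].sum()) if len(table) else 0
    factor = n_tests if (bonferroni and n_tests) else 1
    table["p_adjusted"] = (table["p_value"] * factor).clip(upper=1.0)
    table["significant"] = (
        table["uniquely_abundant"]
        & table["p_adjusted"].notna()
        & (table["p_adjusted"] < alpha)
    )
    return table


def export_heatmap_json(matrix: ScoreMatrix, path) -> None:
    """Write the score matrix as a heatmap-viewer JSON document."""
    doc = {
        "organisms": matrix.organisms,
        "classes": matrix.classes,
        "scores": matrix.scores.to_numpy().astype(int).tolist(),
    }
    with open(path, "w") as out:
        json.dump(doc, out, separators=(",", ":"))


def load_heatmap_json(path) -> ScoreMatrix:
    """Round-trip loader for :func:`export_heatmap_json`."""
    with open(path) as handle:
        doc = json.load(handle)
    frame = pd.DataFrame(
        np.asarray(doc["scores"], dtype=int),
        index=doc["organisms"],
        columns=doc["classes"],
    )
    return ScoreMatrix(scores=frame)
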