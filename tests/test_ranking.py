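"""Enrichment scoring, matrix invariants, clustering and signature tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from ssrscape.motifs import class_order
from ssrscape.ranking import (
    ScoreMatrix,
    build_score_matrix,
    cluster_classes,
    export_heatmap_json,
    load_heatmap_json,
    rank_classes,
    scan_signatures,
    score_organism,
    signature_test,
)
from ssrscape.simulate import simulate_cohort_stats

from .reference import ref_average_linkage, ref_leaf_order

CLASSES = class_order(6)


def _stats_from_density(density: dict[str, float], frequency: dict[str, int] | None = None):
    frequency = frequency or {}
    return pd.DataFrame(
        {
            "organism_id": "org",
            "repeat_class": CLASSES,
            "frequency": [frequency.get(c, 1000 if density.get(c, 0) else 0) for c in CLASSES],
            "density": [density.get(c, 0.0) for c in CLASSES],
        }
    )


def test_top_rank_scores_three():
    stats = _stats_from_density({"A": 500.0, "AC": 100.0}, {"A": 5000, "AC": 50})
    scores = score_organism(stats)
    assert scores["A"] == 3
    assert scores["AC"] == 3  # second-densest, still top 10


def test_low_frequency_overrides_rank():
    stats = _stats_from_density(
        {c: 100.0 - i for i, c in enumerate(CLASSES[:20])},
        {c: (3 if c == CLASSES[7] else 50) for c in CLASSES[:20]},
    )
    scores = score_organism(stats)
    assert scores[CLASSES[7]] == -2  # rank 8 but frequency 3


def test_exactly_ten_frequent_classes():
    dens = {c: 100.0 - i for i, c in enumerate(CLASSES[:10])}
    freq = {c: 50 for c in CLASSES[:10]}
    stats = _stats_from_density(dens, freq)
    scores = score_organism(stats)
    assert (scores[CLASSES[:10]] == 3).all()
    assert (scores.drop(CLASSES[:10]) == -2).all()


def test_score_bands_and_bottom_ranks():
    dens = {c: 1000.0 - i for i, c in enumerate(CLASSES)}
    freq = {c: 100 for c in CLASSES}
    scores = score_organism(_stats_from_density(dens, freq))
    values = scores.to_numpy()
    assert (values[:10] == 3).all()
    assert (values[10:25] == 2).all()
    assert (values[25:100] == 1).all()
    assert (values[100:401] == 0).all()
    assert (values[401:] == -1).all()


def test_rank_ties_are_deterministic():
    dens = {c: 5.0 for c in CLASSES[:3]}
    freq = {CLASSES[0]: 10, CLASSES[1]: 30, CLASSES[2]: 30}
    ranks = rank_classes(_stats_from_density(dens, freq))
    # frequency desc breaks the density tie, then lexicographic ("AC" < "C")
    assert ranks[CLASSES[2]] < ranks[CLASSES[1]] < ranks[CLASSES[0]]


def test_score_invariance_under_scaling_and_frequency_shift():
    stats = simulate_cohort_stats(1, seed=9)
    base = score_organism(stats)
    scaled = stats.copy()
    scaled["density"] *= 7.3
    assert (score_organism(scaled) == base).all()
    shifted = stats.copy()
    mask = shifted["frequency"] >= 10
    shifted.loc[mask, "frequency"] += 1234
    assert (score_organism(shifted) == base).all()


def test_matrix_invariants_on_random_cohorts():
    for seed in range(5):
        stats = simulate_cohort_stats(6, seed=seed)
        matrix = build_score_matrix(stats).scores
        arr = matrix.to_numpy()
        assert set(np.unique(arr)) <= {-2, -1, 0, 1, 2, 3}
        assert ((arr == 3).sum(axis=1) <= 10).all()
        assert ((arr >= 2).sum(axis=1) <= 25).all()
        assert ((arr >= 1).sum(axis=1) <= 100).all()
        freq = stats.pivot(index="organism_id", columns="repeat_class", values="frequency")
        freq = freq.loc[matrix.index, matrix.columns]
        assert (arr[freq.to_numpy() < 10] == -2).all()


def test_build_matrix_row_order_and_duplicates():
    stats = simulate_cohort_stats(3, seed=1)
    order = ["org03", "org01", "org02"]
    matrix = build_score_matrix(stats, order)
    assert matrix.organisms == order
    with pytest.raises(ValueError):
        build_score_matrix(stats, ["org01", "org01", "org02"])


def test_block_diagonal_cohort():
    rows = []
    for i, org in enumerate(["o1", "o2", "o3"]):
        planted = CLASSES[i * 5 : i * 5 + 5]
        rows.append(
            pd.DataFrame(
                {
                    "organism_id": org,
                    "repeat_class": CLASSES,
                    "frequency": [100 if c in planted else 0 for c in CLASSES],
                    "density": [50.0 if c in planted else 0.0 for c in CLASSES],
                }
            )
        )
    matrix = build_score_matrix(pd.concat(rows)).scores
    for i, org in enumerate(["o1", "o2", "o3"]):
        planted = CLASSES[i * 5 : i * 5 + 5]
        assert (matrix.loc[org, planted] == 3).all()
        assert (matrix.loc[org].drop(planted) == -2).all()


def test_heatmap_json_roundtrip(tmp_path):
    stats = simulate_cohort_stats(4, seed=2)
    matrix = build_score_matrix(stats)
    path = tmp_path / "heatmap.json"
    export_heatmap_json(matrix, path)
    back = load_heatmap_json(path)
    pd.testing.assert_frame_equal(back.scores, matrix.scores)


def test_identical_columns_cluster_adjacent():
    frame = pd.DataFrame(
        [[0, 3, 3, 1], [0, 3, 3, 0], [1, 3, 3, 2]],
        index=["o1", "o2", "o3"],
        columns=["w", "x", "y", "z"],
    )
    order, _ = cluster_classes(ScoreMatrix(scores=frame))
    ix, iy = order.index("x"), order.index("y")
    assert abs(ix - iy) == 1


def test_cluster_order_matches_bruteforce_reference(rng):
    cols = rng.integers(-2, 4, size=(6, 8)).astype(float)
    # nudge to make all pairwise distances distinct (no tie ambiguity)
    cols += rng.normal(0, 1e-3, size=cols.shape)
    frame = pd.DataFrame(cols, index=[f"o{i}" for i in range(6)],
                         columns=[f"c{j}" for j in range(8)])
    order, linkage = cluster_classes(ScoreMatrix(scores=frame))
    ref_link = ref_average_linkage(list(cols.T))
    ref_order = ref_leaf_order(ref_link, 8)
    assert [frame.columns[i] for i in ref_order] == order
    for (a, b, d, size), row in zip(ref_link, linkage):
        assert {int(row[0]), int(row[1])} == {a, b}
        assert row[2] == pytest.approx(d)
        assert int(row[3]) == size


def test_signature_uniquely_abundant_and_pvalue():
    clades = {"cl": ["org01", "org02", "org03", "org04"]}
    stats = simulate_cohort_stats(
        12, clades, {"cl": "AACAGC"}, signature_fold=10, seed=4
    )
    res = signature_test("AACAGC", clades["cl"], stats)
    assert res.uniquely_abundant
    assert res.p_value is not None and res.p_value < 0.05


def test_signature_improper_clade_errors():
    stats = simulate_cohort_stats(4, seed=0)
    with pytest.raises(ValueError):
        signature_test("AC", [f"org{i:02d}" for i in range(1, 5)], stats)


def test_identical_densities_not_uniquely_abundant():
    rows = []
    for org in ["o1", "o2", "o3", "o4", "o5"]:
        rows.append(
            pd.DataFrame(
                {
                    "organism_id": org,
                    "repeat_class": CLASSES,
                    "frequency": 100,
                    "density": np.linspace(501, 1, len(CLASSES)),
                }
            )
        )
    stats = pd.concat(rows)
    res = signature_test(CLASSES[0], ["o1", "o2"], stats)
    # top-10 everywhere, hence not *uniquely* abundant; degenerate variance -> no p
    assert not res.uniquely_abundant
    assert res.p_value is None


def test_scan_signatures_flags_only_planted():
    clades = {
        "cA": ["org01", "org02", "org03", "org04"],
        "cB": ["org05", "org06", "org07", "org08"],
        "cC": ["org09", "org10", "org11", "org12"],
    }
    sigs = {"cA": "AACAGC", "cB": "ACGCGG", "cC": "AATGG"}
    stats = simulate_cohort_stats(12, clades, sigs, signature_fold=10, seed=7)
    table = scan_signatures(stats, clades)
    flagged = table[table["uniquely_abundant"] & (table["p_value"] < 0.05)]
    assert set(zip(flagged["clade"], flagged["repeat_class"])) == set(sigs.items())
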