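from __future__ import annotations

import numpy as np
import pytest

from ssrscape import (
    CohortConfig,
    CohortPlan,
    GeneModel,
    PeakPlan,
    PlantedRepeat,
    SyntheticGenomeSpec,
    bump_histogram,
    generate_cohort,
    generate_genome,
    run_cohort,
    write_cohort,
)


@pytest.fixture(scope="session")
def small_genome():
    """One 50 kb genome with planted repeats in exon, intron and intergenic space."""
    spec = SyntheticGenomeSpec(
        organism_id="orgA",
        genome_length=50_000,
        background_gc=0.42,
        rng_seed=5,
        planted=[
            PlantedRepeat("AC", 24, 2100),
            PlantedRepeat("AAG", 24, 3000),
            PlantedRepeat("AAAT", 52, 30_000),
            PlantedRepeat("GATA", 48, 40_000),
        ],
        genes=[
            GeneModel("g1", 2000, 6000, "+", ((2000, 2500), (3500, 4000))),
            GeneModel("g2", 9000, 12_000, "-", ((9000, 12_000),)),
        ],
    )
    return generate_genome(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Six organisms, two subgroups, one planted clade signature and one peak."""
    plan = CohortPlan(
        n_organisms=6,
        genome_length=60_000,
        seed=11,
        subgroup_of={f"org{i:02d}": ("sgA" if i <= 3 else "sgB") for i in range(1, 7)},
        clades={"sgA": ["org01", "org02", "org03"]},
        signatures={"sgA": "AACAGC"},
        peaks={"org04": [PeakPlan("AACCCT", bump_histogram(4, 5, 30, 20))]},
    )
    return generate_cohort(plan)


@pytest.fixture(scope="session")
def cohort_run(small_cohort, tmp_path_factory):
    """The small cohort written to disk and pushed through the full pipeline."""
    root = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, root / "data")
    config = CohortConfig(
        manifest_path=root / "data" / "manifest.tsv", output_dir=root / "results"
    )
    written = run_cohort(config)
    return small_cohort, root, written


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240)
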