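"""The whole pipeline over a synthetic cohort, from FASTA to report tables.

Generates five organisms (one clade with a planted signature class, one
organism with a planted length-preference bump), writes FASTA + manifest,
and runs detection -> attributes -> scoring -> signatures -> peaks in one
call. Rerunning with the same seed reproduces every output byte for byte.
"""

import tempfile
from pathlib import Path

import pandas as pd

from ssrscape import (
    CohortConfig,
    CohortPlan,
    PeakPlan,
    bump_histogram,
    generate_cohort,
    run_cohort,
    write_cohort,
)

plan = CohortPlan(
    n_organisms=5,
    genome_length=60_000,
    seed=11,
    subgroup_of={"org01": "sgA", "org02": "sgA", "org03": "sgA",
                 "org04": "sgB", "org05": "sgB"},
    clades={"sgA": ["org01", "org02", "org03"]},
    signatures={"sgA": "AACAGC"},
    peaks={"org04": [PeakPlan("AACCCT", bump_histogram(4, 5, 30, 20))]},
)
cohort = generate_cohort(plan)

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    write_cohort(cohort, root / "data")
    written = run_cohort(
        CohortConfig(manifest_path=root / "data" / "manifest.tsv",
                     output_dir=root / "results")
    )
    print("outputs written:")
    for key in sorted(written):
        print(" ", key)

    master = pd.read_csv(written["master_table"], sep="\t", comment="#")
    print("\nmaster table:")
    print(master[["organism_id", "subgroup", "ssr_frequency", "ssr_density"]]
          .to_string(index=False))

    sig = pd.read_csv(written["signatures"], sep="\t")
    print("\nsignificant clade signatures:")
    print(sig[sig["significant"]][["clade", "repeat_class", "p_value"]]
          .to_string(index=False))

    peaks = pd.read_csv(written["peaks"], sep="\t")
    print("\nlength-preference peaks:")
    print(peaks.to_string(index=False))
# The clade signature (sgA, AACAGC) and the planted peak (org04, AACCCT)
# both come back out of the end-to-end run.
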