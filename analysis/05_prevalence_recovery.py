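#!/usr/bin/env python
"""Parameter recovery: does the pipeline recover effect prevalence?

Simulates high-SNR cohorts of 18 subjects in which 0, 8 or 18 subjects
express a target-vs-distractor ERP effect, runs the per-subject
permutation test and counts subjects with a significant bin in the
150-450 ms window.  Writes results/prevalence_recovery.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from oddball_consistency.experiments import prevalence_recovery

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    out = prevalence_recovery(prevalences=(0.0, 8.0 / 18.0, 1.0),
                              n_subjects=18, master_seed=SEED,
                              n_permutations=200, include_p300_check=True)
    table = pd.DataFrame({
        "prevalence": out["prevalences"],
        "expressing_subjects": out["expressing"],
        "recovered_successes": out["successes"],
        "expected": out["expected"],
    })
    Path("results").mkdir(exist_ok=True)
    table.to_csv(Path("results/prevalence_recovery.csv"), index=False)
    print(table.to_string(index=False))
    print(f"\nP300 windows significant in every subject at prevalence 1: "
          f"{out.get('p300_rows_all_true')}")


if __name__ == "__main__":
    main()
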