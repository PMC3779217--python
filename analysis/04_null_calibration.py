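#!/usr/bin/env python
"""Family-wise error calibration of the max-statistic permutation test.

Measures, on pure-noise datasets (5 electrodes x 250 time points, 200
permutations each), the fraction of datasets with any significant point at
the corrected alpha 0.05/3, for both tail conventions, plus the same check
on fully synthetic zero-effect cohorts.  Writes
results/null_calibration.json.
"""

import json
import sys
from pathlib import Path

from oddball_consistency.experiments import (fwer_null_experiment,
                                             simulator_null_experiment)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    out = {
        "split": fwer_null_experiment(n_datasets=200, n_permutations=200,
                                      seed=SEED, tail_mode="split"),
        "per_tail": fwer_null_experiment(n_datasets=200, n_permutations=200,
                                         seed=SEED, tail_mode="per-tail"),
        "simulator_null_split": simulator_null_experiment(
            n_cohorts=50, n_permutations=200, seed=SEED),
    }
    Path("results").mkdir(exist_ok=True)
    Path("results/null_calibration.json").write_text(json.dumps(out, indent=1))
    print(f"split-tail FWER:    {out['split']['fwer']:.3f} "
          f"(bound {out['split']['bound']:.3f})")
    print(f"per-tail FWER:      {out['per_tail']['fwer']:.3f} "
          f"(~2x corrected alpha by construction)")
    print(f"simulator null:     {out['simulator_null_split']['fwer']:.3f}")
    print("Wrote results/null_calibration.json")


if __name__ == "__main__":
    main()
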