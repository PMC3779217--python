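#!/usr/bin/env python
"""Simulate the default 18-subject oddball cohort and write epoch containers.

Each subject gets 300 standard / 50 target / 50 distractor epochs (15
channels, 250 Hz, -600..+1600 ms) with the default effect structure:
deviant N1/P3a/P3b/LNC components, delta-theta power increase, alpha
decrease, target-vs-distractor prevalence 8/18.  Epoch containers go under
scratch/run_default/ (binary, regenerable); a cohort summary table goes to
results/cohort_summary.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from oddball_consistency.config import ParadigmConfig
from oddball_consistency.containers import write_epochs
from oddball_consistency.simulate import default_effects, simulate_subject

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("scratch/run_default")
RESULTS = Path("results")


def main() -> None:
    paradigm = ParadigmConfig()
    effects = default_effects()
    rows = []
    for idx in range(18):
        profile, epochs = simulate_subject(paradigm, effects, SEED, idx)
        write_epochs(epochs, OUT / "subjects" / profile.subject_id,
                     provenance={"master_seed": SEED, "subject_index": idx})
        rows.append({
            "subject": profile.subject_id,
            "n_trials": epochs.n_trials,
            "expresses_td_effect": profile.expresses_td_effect,
            "alpha_sign": profile.oscillation_sign.get("alpha", 1.0),
            "noise_level_uV": round(profile.noise_level_uV, 2),
        })
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "cohort_summary.csv", index=False)
    n_expr = table["expresses_td_effect"].sum()
    n_flip = (table["alpha_sign"] < 0).sum()
    print(f"Simulated 18 subjects (seed {SEED}): {n_expr} express the "
          f"target-vs-distractor effect, {n_flip} show the inverted alpha "
          f"response. Containers in {OUT}, summary in results/cohort_summary.csv")


if __name__ == "__main__":
    main()
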