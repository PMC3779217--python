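"""Reusable study-level experiments: null calibration, prevalence recovery
and paradigm checks.

These functions recompute the pipeline's headline quantities from scratch
— they are shared by the test suite, the acceptance script and the
analysis drivers so that every reported number comes from one code path.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import erp, permstat
from .config import ArtifactCriteria, ParadigmConfig, PermTestConfig
from .consistency import EffectWindow, window_effect
from .preprocess import artifact_scan
from .simulate import (EffectConfig, default_effects, draw_subject_profile,
                       generate_sequence, simulate_subject)

__all__ = ["sequence_check", "fwer_null_experiment",
            "simulator_null_experiment", "prevalence_recovery",
            "high_snr_effects", "TD_WINDOW", "P300_WINDOWS"]

TD_WINDOW = EffectWindow("t-d all 0.15-0.45 s", "target-distractor",
                         150, 450, "all")
P300_WINDOWS = (
    EffectWindow("t-s Fz 0.3-0.4 s", "standard-target", 300, 400, "Fz"),
    EffectWindow("d-s Fz 0.3-0.4 s", "standard-distractor", 300, 400, "Fz"),
)


def sequence_check(n_seeds: int = 1000, base_seed: int = 0,
                   config: ParadigmConfig | None = None) -> dict:
    """Counts and gap-bound violations of the sequence generator over seeds."""
    config = config or ParadigmConfig()
    counts_ok = gaps_ok = 0
    last_counts = {}
    for seed in range(base_seed, base_seed + n_seeds):
        seq = generate_sequence(config, seed)
        last_counts = seq.counts()
        if (last_counts["standard"] == config.n_standard
                and last_counts["target"] == config.n_target
                and last_counts["distractor"] == config.n_distractor):
            counts_ok += 1
        gaps = seq.deviant_gaps()
        if (len(gaps) == config.n_target + config.n_distractor
                and all(config.min_gap <= g <= config.max_gap for g in gaps)
                and sum(gaps) == config.n_standard):
            gaps_ok += 1
    return {
        "n_seeds": n_seeds,
        "n_stimuli": sum(last_counts.values()),
        "n_standard": last_counts.get("standard", 0),
        "n_target": last_counts.get("target", 0),
        "n_distractor": last_counts.get("distractor", 0),
        "count_violations": n_seeds - counts_ok,
        "gap_violations": n_seeds - gaps_ok,
    }


def fwer_null_experiment(n_datasets: int = 200, n_permutations: int = 200,
                         n_electrodes: int = 5, n_times: int = 250,
                         n_a: int = 20, n_b: int = 20, seed: int = 0,
                         tail_mode: str = "split") -> dict:
    """Family-wise error rate of the max-statistic test on pure-noise data.

    Each dataset is exchangeable Gaussian noise on a reduced grid; the
    quantity of interest is the fraction of datasets with *any* point
    significant at the corrected alpha (0.05/3).  ``"split"`` tail mode
    carries the family-wise guarantee at the corrected alpha; the
    ``"per-tail"`` convention bounds each tail separately instead.
    """
    rng = np.random.default_rng(seed)
    config = PermTestConfig(n_permutations=n_permutations,
                            tail_mode=tail_mode, seed=seed)
    geometry = permstat.PointGeometry(
        times_ms=tuple(float(t) for t in range(n_times)),
        channels=tuple(f"ch{i}" for i in range(n_electrodes)))
    n_false = 0
    for _ in range(n_datasets):
        a = rng.standard_normal((n_a, n_times, n_electrodes))
        b = rng.standard_normal((n_b, n_times, n_electrodes))
        res = permstat.permutation_test(a, b, config, geometry, rng=rng)
        n_false += int(res.mask.any())
    rate = n_false / n_datasets
    alpha_corr = config.corrected_alpha
    se = float(np.sqrt(alpha_corr * (1 - alpha_corr) / n_datasets))
    return {"n_datasets": n_datasets, "fwer": rate,
            "corrected_alpha": alpha_corr, "binomial_se": se,
            "bound": alpha_corr + 2 * se}


def _null_paradigm() -> ParadigmConfig:
    # reduced session: 30 standards, 10+10 deviants, gaps 1-2, 5 channels
    return ParadigmConfig(n_standard=30, n_target=10, n_distractor=10,
                          min_gap=1, max_gap=2,
                          channel_names=("Fz", "Cz", "Pz", "O1", "O2"))


def simulator_null_experiment(n_cohorts: int = 50, n_permutations: int = 200,
                              seed: int = 0, tail_mode: str = "split") -> dict:
    """Null calibration on full synthetic epochs with all effects at zero.

    With every component amplitude and power change zero, the three
    conditions are exchangeable and the target-vs-distractor test must
    reject at no more than the corrected alpha rate.
    """
    paradigm = _null_paradigm()
    base = default_effects(channels=paradigm.channel_names,
                           amplitude_scale=0.0, power_scale=0.0,
                           alpha_flip_prob=0.0)
    config = PermTestConfig(n_permutations=n_permutations, tail_mode=tail_mode)
    n_false = 0
    for k in range(n_cohorts):
        _, epochs = simulate_subject(paradigm, base, seed + 7000 + k, 0)
        maps, geometry = erp.erp_point_maps(epochs)
        res = permstat.permutation_test(
            maps["target"], maps["distractor"],
            replace(config, seed=seed + k), geometry,
            rng=np.random.default_rng([seed, 5000 + k]))
        n_false += int(res.mask.any())
    rate = n_false / n_cohorts
    alpha_corr = config.corrected_alpha
    se = float(np.sqrt(alpha_corr * (1 - alpha_corr) / n_cohorts))
    return {"n_cohorts": n_cohorts, "fwer": rate,
            "corrected_alpha": alpha_corr, "bound": alpha_corr + 2 * se}


def high_snr_effects(prevalence_td: float) -> EffectConfig:
    """High signal-to-noise study conditions for parameter recovery."""
    return default_effects(prevalence_td=prevalence_td, noise_level_uV=3.0,
                           amplitude_scale=2.0, alpha_flip_prob=0.0)


def analyze_subject_erp(epochs, perm_config: PermTestConfig,
                        contrasts=permstat.CONTRASTS):
    """Artifact scan + ERP trial maps + permutation contrasts for one subject."""
    mask = artifact_scan(epochs, ArtifactCriteria())
    maps, geometry = erp.erp_point_maps(epochs, mask)
    return permstat.run_contrasts(maps, geometry, perm_config,
                                  subject_id=epochs.subject_id,
                                  contrasts=contrasts)


def prevalence_recovery(prevalences=(0.0, 8.0 / 18.0, 1.0),
                        n_subjects: int = 18, master_seed: int = 0,
                        n_permutations: int = 200,
                        include_p300_check: bool = False,
                        stratified: bool = True) -> dict:
    """Recover effect-table success counts from simulated cohorts.

    For each prevalence pi, simulates a high-SNR cohort in which a fraction
    pi of subjects expresses the target-vs-distractor ERP effect, runs the
    per-subject target-vs-distractor permutation test, and counts subjects
    with a significant bin in the 150-450 ms window over all electrodes.
    With ``stratified`` (the default) exactly round(n*pi) subjects are
    assigned the effect — a random permutation decides which — so the
    recovered count measures analysis error, not binomial sampling noise
    of the cohort draw; the Bernoulli assignment path is exercised by the
    profile Monte-Carlo property instead.  Optionally also verifies the
    P300 windows (deviant vs standard at Fz) for the prevalence-1 cohort.
    """
    from dataclasses import replace as dc_replace

    paradigm = ParadigmConfig()
    out: dict = {"prevalences": list(prevalences), "n_subjects": n_subjects,
                 "successes": [], "expected": [], "expressing": []}
    for k, pi in enumerate(prevalences):
        effects = high_snr_effects(pi)
        cohort_seed = master_seed + 100 * (k + 1)
        expressing_set = None
        if stratified:
            n_expr = int(round(n_subjects * pi))
            order = np.random.default_rng([cohort_seed, 42]).permutation(n_subjects)
            expressing_set = set(order[:n_expr].tolist())
        s_count = 0
        expressing = 0
        p300_all = True
        for idx in range(n_subjects):
            profile = draw_subject_profile(paradigm, effects, cohort_seed, idx)
            if expressing_set is not None:
                profile = dc_replace(profile,
                                     expresses_td_effect=idx in expressing_set)
            profile, epochs = simulate_subject(paradigm, effects, cohort_seed,
                                               idx, profile=profile)
            expressing += int(profile.expresses_td_effect)
            perm_cfg = PermTestConfig(n_permutations=n_permutations,
                                      seed=cohort_seed + idx)
            contrasts = [("target", "distractor")]
            if include_p300_check and pi == 1.0:
                contrasts = [("standard", "target"), ("standard", "distractor"),
                             ("target", "distractor")]
            results = analyze_subject_erp(epochs, perm_cfg, contrasts)
            if window_effect(results["target-distractor"], TD_WINDOW):
                s_count += 1
            if include_p300_check and pi == 1.0:
                for w in P300_WINDOWS:
                    if not window_effect(results[w.contrast], w):
                        p300_all = False
        out["successes"].append(s_count)
        out["expected"].append(n_subjects * pi)
        out["expressing"].append(expressing)
        if include_p300_check and pi == 1.0:
            out["p300_rows_all_true"] = p300_all
    return out
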