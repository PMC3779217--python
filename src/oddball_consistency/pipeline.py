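"""Pipeline orchestration: simulate -> preprocess -> erp/tfr -> stats ->
consistency -> report, with disk hand-off between stages, structured
logging and a reproducibility manifest.

Each stage reads only the declared outputs of its upstream stage from the
run directory, so stages can be re-run individually; re-running with an
identical configuration reproduces byte-identical numeric outputs.  The
manifest records the configuration hash, the master seed and a sha256 of
every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import consistency as cons
from . import containers, erp, permstat, preprocess, timefreq
from .config import (ArtifactCriteria, ConfigurationError, FilterSpec,
                     ParadigmConfig, PermTestConfig, StftConfig, config_hash)
from .simulate import EffectConfig, default_effects, simulate_subject

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "erp", "tfr", "stats", "consistency",
          "report")


class DependencyError(RuntimeError):
    """A stage's upstream output is missing from the run directory."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run depends on."""

    master_seed: int = 0
    n_subjects: int = 18
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    effects: EffectConfig = field(default_factory=default_effects)
    recording_filter: FilterSpec = field(default_factory=FilterSpec)
    artifact_criteria: ArtifactCriteria = field(default_factory=ArtifactCriteria)
    stft: StftConfig = field(default_factory=StftConfig)
    perm: PermTestConfig = field(default_factory=PermTestConfig)
    binomial_p0: float = 0.05

    def fast(self) -> "RunConfig":
        """Reduced profile: 6 subjects, 200 permutations."""
        return replace(self, n_subjects=min(self.n_subjects, 6),
                       perm=replace(self.perm, n_permutations=200))

    def hash(self) -> str:
        return config_hash(self.paradigm, self.recording_filter,
                           self.artifact_criteria, self.stft, self.perm,
                           {"master_seed": self.master_seed,
                            "n_subjects": self.n_subjects,
                            "binomial_p0": self.binomial_p0})


def _subject_ids(config: RunConfig) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(config.n_subjects)]


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {needed_by!r} needs output of {stage!r}: {path} is missing"
        )
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, out: Path) -> None:
    for idx in range(config.n_subjects):
        profile, epochs = simulate_subject(config.paradigm, config.effects,
                                           config.master_seed, idx)
        containers.write_epochs(
            epochs, out / "subjects" / profile.subject_id,
            provenance={"config_hash": config.hash(),
                        "master_seed": config.master_seed,
                        "subject_index": idx,
                        "expresses_td_effect": profile.expresses_td_effect,
                        "profile_seed": profile.rng_seed},
        )
        logger.info("simulated %s (%d trials)", profile.subject_id,
                    epochs.n_trials)


def stage_preprocess(config: RunConfig, out: Path) -> None:
    rows = []
    for subj in _subject_ids(config):
        src = _require(out / "subjects" / subj, "simulate", "preprocess")
        epochs = containers.read_epochs(src)
        filtered = preprocess.zero_phase_bandpass(epochs, config.recording_filter)
        mask = preprocess.artifact_scan(filtered, config.artifact_criteria)
        containers.write_epochs(filtered, out / "preprocessed" / subj,
                                provenance={"config_hash": config.hash()})
        keep_path = out / "preprocessed" / subj / "keep_mask.json"
        keep_path.write_text(json.dumps({
            "keep": mask.keep.astype(int).tolist(),
            "rules_violated": [list(r) for r in mask.rules_violated],
        }))
        for i, (kept, rules) in enumerate(zip(mask.keep, mask.rules_violated)):
            rows.append({"subject": subj, "trial": i, "kept": bool(kept),
                         "rules_violated": ";".join(rules)})
        logger.info("preprocessed %s: kept %d/%d trials", subj, mask.n_kept,
                    epochs.n_trials)
    pd.DataFrame(rows).to_csv(out / "artifact_report.csv", index=False)


def _load_preprocessed(config: RunConfig, out: Path, subj: str):
    src = _require(out / "preprocessed" / subj, "preprocess", "analysis")
    epochs = containers.read_epochs(src)
    keep_doc = json.loads((src / "keep_mask.json").read_text())
    mask = preprocess.EpochMask(
        keep=np.array(keep_doc["keep"], dtype=bool),
        rules_violated=[tuple(r) for r in keep_doc["rules_violated"]],
    )
    return epochs, mask


def stage_erp(config: RunConfig, out: Path) -> None:
    erp_dir = out / "erp"
    erp_dir.mkdir(parents=True, exist_ok=True)
    for subj in _subject_ids(config):
        epochs, mask = _load_preprocessed(config, out, subj)
        erps = erp.erp_pipeline(epochs, mask)
        for cond, e in erps.items():
            containers.write_array(e.data, erp_dir / subj, f"erp_{cond}",
                                   meta={"times_ms": e.times_ms.tolist(),
                                         "channels": list(e.channel_names),
                                         "n_trials": e.n_trials})
        gfp_rows = {"time_ms": erps["standard"].times_ms}
        scalp_frames = []
        for a, b, rng_ms in (("target", "standard", (300, 400)),
                             ("distractor", "standard", (300, 400)),
                             ("target", "distractor", (200, 400))):
            diff = erp.difference_wave(erps[a], erps[b])
            gfp_rows[f"gfp_{a}-{b}_uV"] = erp.gfp(diff)
            table = erp.scalp_map_windows(diff, rng_ms, 20.0)
            table.insert(0, "contrast", f"{a}-{b}")
            scalp_frames.append(table)
        pd.DataFrame(gfp_rows).to_csv(erp_dir / f"gfp_{subj}.csv", index=False)
        pd.concat(scalp_frames).to_csv(erp_dir / f"scalpmaps_{subj}.csv",
                                       index=False)
        logger.info("ERP stage done for %s", subj)


def stage_tfr(config: RunConfig, out: Path) -> None:
    tfr_dir = out / "tfr"
    tfr_dir.mkdir(parents=True, exist_ok=True)
    for subj in _subject_ids(config):
        epochs, mask = _load_preprocessed(config, out, subj)
        maps, t_ms, f_hz = timefreq.tfr_trial_maps(epochs, mask, config.stft)
        diffs, _, bounds = timefreq.condition_differences(maps)
        rows = []
        for contrast, d in diffs.items():
            tt, ff, cc = np.meshgrid(t_ms, f_hz, np.arange(len(epochs.channel_names)),
                                     indexing="ij")
            rows.append(pd.DataFrame({
                "contrast": contrast, "time_ms": tt.ravel(),
                "freq_hz": ff.ravel(),
                "electrode": np.asarray(epochs.channel_names)[cc.ravel()],
                "value": d.ravel(),
            }))
        pd.concat(rows).to_csv(tfr_dir / f"tfr_diff_{subj}.csv", index=False)
        (tfr_dir / f"tfr_meta_{subj}.json").write_text(json.dumps({
            "time_centers_ms": t_ms.tolist(), "freq_centers_hz": f_hz.tolist(),
            "normalization_bounds": bounds,
        }))
        logger.info("TFR stage done for %s", subj)


def _save_result(res: permstat.SignificanceResult, directory: Path,
                 name: str) -> None:
    containers.write_array(res.t_obs, directory, f"{name}_t")
    containers.write_array(res.p, directory, f"{name}_p")
    containers.write_array(res.mask.astype(float), directory, f"{name}_mask")
    (directory / f"{name}.json").write_text(json.dumps({
        "contrast": res.contrast, "subject_id": res.subject_id,
        "times_ms": list(res.geometry.times_ms),
        "channels": list(res.geometry.channels),
        "freqs_hz": (list(res.geometry.freqs_hz)
                     if res.geometry.freqs_hz is not None else None),
        "n_permutations": res.null.n_permutations,
        "exact": res.null.exact,
        "corrected_alpha": res.config.corrected_alpha,
        "tail_mode": res.config.tail_mode,
        "seed": res.config.seed,
        "n_untestable": res.n_untestable,
        "n_significant": res.n_significant,
        "null_minima": res.null.minima.tolist(),
        "null_maxima": res.null.maxima.tolist(),
    }))


def _load_result(directory: Path, name: str,
                 config: PermTestConfig) -> permstat.SignificanceResult:
    doc = json.loads((directory / f"{name}.json").read_text())
    t, _ = containers.read_array(directory, f"{name}_t")
    p, _ = containers.read_array(directory, f"{name}_p")
    mask, _ = containers.read_array(directory, f"{name}_mask")
    geo = permstat.PointGeometry(
        times_ms=tuple(doc["times_ms"]), channels=tuple(doc["channels"]),
        freqs_hz=tuple(doc["freqs_hz"]) if doc["freqs_hz"] else None)
    null = permstat.NullHistograms(
        minima=np.array(doc["null_minima"]), maxima=np.array(doc["null_maxima"]),
        exact=doc["exact"], n_permutations=doc["n_permutations"])
    return permstat.SignificanceResult(
        t_obs=t, p=p, mask=mask.astype(bool), null=null, geometry=geo,
        contrast=doc["contrast"], config=config,
        subject_id=doc["subject_id"], n_untestable=doc["n_untestable"])


def stage_stats(config: RunConfig, out: Path) -> None:
    stats_dir = out / "stats"
    has_tfr = (out / "tfr").exists()
    if not has_tfr:
        logger.info("TFR outputs absent: running ERP statistics only")
    for s_idx, subj in enumerate(_subject_ids(config)):
        epochs, mask = _load_preprocessed(config, out, subj)
        perm_cfg = replace(config.perm,
                           seed=int(np.random.default_rng(
                               [config.master_seed, 4000 + s_idx]
                           ).integers(0, 2**31 - 1)))
        maps, geo = erp.erp_point_maps(epochs, mask)
        results = permstat.run_contrasts(maps, geo, perm_cfg, subject_id=subj)
        for contrast, res in results.items():
            _save_result(res, stats_dir / subj, f"erp_{contrast}")
        if has_tfr:
            tmaps, t_ms, f_hz = timefreq.tfr_trial_maps(epochs, mask, config.stft)
            tgeo = permstat.PointGeometry(times_ms=tuple(t_ms),
                                          channels=epochs.channel_names,
                                          freqs_hz=tuple(f_hz))
            tresults = permstat.run_contrasts(tmaps, tgeo, perm_cfg,
                                              subject_id=subj)
            for contrast, res in tresults.items():
                _save_result(res, stats_dir / subj, f"tfr_{contrast}")


def stage_consistency(config: RunConfig, out: Path) -> None:
    stats_dir = _require(out / "stats", "stats", "consistency")
    cons_dir = out / "consistency"
    cons_dir.mkdir(parents=True, exist_ok=True)
    domains = []
    results: dict[str, dict[str, dict[str, permstat.SignificanceResult]]] = {}
    for subj in _subject_ids(config):
        subj_dir = _require(stats_dir / subj, "stats", "consistency")
        results[subj] = {}
        for domain in ("erp", "tfr"):
            dom: dict[str, permstat.SignificanceResult] = {}
            for a, b in permstat.CONTRASTS:
                name = f"{domain}_{a}-{b}"
                if (subj_dir / f"{name}.json").exists():
                    dom[f"{a}-{b}"] = _load_result(subj_dir, name, config.perm)
            if dom:
                results[subj][domain] = dom
                if domain not in domains:
                    domains.append(domain)
    if "tfr" not in domains:
        logger.info("no TFR statistics found: consistency restricted to ERP windows")

    for domain in domains:
        for a, b in permstat.CONTRASTS:
            contrast = f"{a}-{b}"
            masks = [results[s][domain][contrast] for s in results]
            counts = cons.count_subjects(masks)
            geo = masks[0].geometry
            containers.write_array(
                counts.astype(float), cons_dir, f"subject_counts_{domain}_{contrast}",
                meta={"times_ms": list(geo.times_ms),
                      "channels": list(geo.channels),
                      "freqs_hz": (list(geo.freqs_hz)
                                   if geo.freqs_hz is not None else None)})
    table = cons.build_effect_table(results, p0=config.binomial_p0,
                                    domains=tuple(domains))
    table.display().to_csv(cons_dir / "effect_table.csv")
    logger.info("effect table:\n%s", table.display().to_string())


def stage_report(config: RunConfig, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cons_dir = _require(out / "consistency", "consistency", "report")
    rep_dir = out / "report"
    rep_dir.mkdir(parents=True, exist_ok=True)
    for a, b in permstat.CONTRASTS:
        contrast = f"{a}-{b}"
        erp_name = f"subject_counts_erp_{contrast}"
        if (cons_dir / f"{erp_name}.json").exists():
            counts, meta = containers.read_array(cons_dir, erp_name)
            fig, ax = plt.subplots(figsize=(8, 4))
            ax.plot(meta["times_ms"], counts)
            ax.set_xlabel("time (ms)")
            ax.set_ylabel("subjects significant")
            ax.set_title(f"ERP consistency: {contrast}")
            fig.savefig(rep_dir / f"erp_counts_{contrast}.png", dpi=100)
            plt.close(fig)
        tfr_name = f"subject_counts_tfr_{contrast}"
        if (cons_dir / f"{tfr_name}.json").exists():
            counts, meta = containers.read_array(cons_dir, tfr_name)
            fig, ax = plt.subplots(figsize=(6, 4))
            im = ax.imshow(counts.max(axis=2).T, aspect="auto", origin="lower",
                           extent=(meta["times_ms"][0], meta["times_ms"][-1],
                                   meta["freqs_hz"][0], meta["freqs_hz"][-1]))
            fig.colorbar(im, ax=ax, label="subjects significant (max over electrodes)")
            ax.set_xlabel("time (ms)")
            ax.set_ylabel("frequency (Hz)")
            ax.set_title(f"TFR consistency: {contrast}")
            fig.savefig(rep_dir / f"tfr_counts_{contrast}.png", dpi=100)
            plt.close(fig)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "erp": stage_erp,
    "tfr": stage_tfr,
    "stats": stage_stats,
    "consistency": stage_consistency,
    "report": stage_report,
}


def run(config: RunConfig, stages=STAGES, out_dir="runs/run0") -> dict:
    """Run the requested stages in dependency order; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    for stage in ordered:
        logger.info("=== stage %s ===", stage)
        _STAGE_FUNCS[stage](config, out)

    hashes = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            hashes[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    manifest = {
        "config_hash": config.hash(),
        "master_seed": config.master_seed,
        "n_subjects": config.n_subjects,
        "stages": ordered,
        "outputs": hashes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
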