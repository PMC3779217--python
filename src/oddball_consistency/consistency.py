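"""Cross-subject consistency of single-subject significance maps.

Per-subject corrected masks are aggregated three ways: (1) subject-count
maps — how many subjects are significant at the same exact analysis point;
(2) named effect windows — a subject shows an effect when at least one
significant bin falls anywhere inside a window's time range x electrode
set (x frequency band), so subjects need not overlap in time; and (3)
one-sided exact binomial group tests of whether the number of subjects
with an effect exceeds chance at a per-subject base rate p0 (0.05 by
default, kept at the nominal single-test level rather than the corrected
alpha/3; a flag switches to the corrected rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError
from .permstat import PointGeometry, SignificanceResult

__all__ = ["ELECTRODE_GROUPS", "EffectWindow", "EffectTable",
           "count_subjects", "window_effect", "best_electrode",
           "binomial_group_test", "build_effect_table",
           "default_effect_windows", "resolve_electrodes"]

logger = logging.getLogger(__name__)

# Standard 10-20 group membership for the 15 analysed electrodes.
ELECTRODE_GROUPS: dict[str, tuple[str, ...]] = {
    "frontal": ("F3", "F4", "F7", "F8", "Fz"),
    "central": ("C3", "C4", "Cz"),
    "parietal": ("P3", "P4", "P7", "P8", "Pz"),
    "occipital": ("O1", "O2"),
}
ELECTRODE_GROUPS["fpc"] = (ELECTRODE_GROUPS["frontal"]
                           + ELECTRODE_GROUPS["parietal"]
                           + ELECTRODE_GROUPS["central"])
ELECTRODE_GROUPS["po"] = (ELECTRODE_GROUPS["parietal"]
                          + ELECTRODE_GROUPS["occipital"])


@dataclass(frozen=True)
class EffectWindow:
    """A named time-range x electrode-set (x band) region of interest.

    ``electrodes`` is a named group ("fpc", "po", "all", any key of
    ``ELECTRODE_GROUPS``), a single electrode name, or an explicit tuple.
    Boundaries are inclusive at both ends on every axis.
    """

    name: str
    contrast: str
    t_start_ms: float
    t_end_ms: float
    electrodes: str | tuple[str, ...] = "all"
    band_hz: tuple[float, float] | None = None
    domain: str = "erp"


@dataclass
class EffectTable:
    """Subject x window boolean matrix plus binomial group p-values."""

    table: pd.DataFrame          # rows: windows, columns: subjects (bool)
    successes: pd.Series         # per-window subject count s
    p_binomial: pd.Series        # per-window one-sided exact p
    n_subjects: int
    p0: float

    def display(self) -> pd.DataFrame:
        """Summary table in the x/blank style with s and p columns."""
        disp = self.table.map(lambda v: "x" if v else "")
        disp["s"] = self.successes
        disp["p"] = self.p_binomial.round(2)
        return disp


def resolve_electrodes(spec, channels: tuple[str, ...]) -> tuple[str, ...]:
    if isinstance(spec, str):
        if spec == "all":
            names = channels
        elif spec in ELECTRODE_GROUPS:
            names = ELECTRODE_GROUPS[spec]
        elif spec in channels:
            names = (spec,)
        else:
            raise ConfigurationError(f"unknown electrode set {spec!r}")
    else:
        names = tuple(spec)
    bad = [n for n in names if n not in channels]
    if bad:
        raise ConfigurationError(f"electrodes not in channel list: {bad}")
    if not names:
        raise ConfigurationError("empty electrode set")
    return tuple(n for n in names if n in channels)


def _window_index(geometry: PointGeometry, window: EffectWindow) -> np.ndarray:
    """Boolean index over the geometry's point grid (inclusive bounds)."""
    times = np.asarray(geometry.times_ms)
    t_sel = (times >= window.t_start_ms - 1e-9) & (times <= window.t_end_ms + 1e-9)
    electrodes = resolve_electrodes(window.electrodes, geometry.channels)
    ch_sel = np.array([c in electrodes for c in geometry.channels])
    if geometry.freqs_hz is None:
        return t_sel[:, None] & ch_sel[None, :]
    freqs = np.asarray(geometry.freqs_hz)
    if window.band_hz is None:
        f_sel = np.ones(len(freqs), dtype=bool)
    else:
        f_sel = (freqs >= window.band_hz[0] - 1e-9) & \
                (freqs <= window.band_hz[1] + 1e-9)
    return t_sel[:, None, None] & f_sel[None, :, None] & ch_sel[None, None, :]


def count_subjects(masks: list[SignificanceResult]) -> np.ndarray:
    """Per-point count of subjects simultaneously significant."""
    if not masks:
        raise ConfigurationError("no masks given")
    geo = masks[0].geometry
    for r in masks[1:]:
        if r.geometry.shape != geo.shape:
            raise ConfigurationError("masks have mismatching point geometry")
    return np.sum([r.mask.astype(int) for r in masks], axis=0)


def window_effect(result: SignificanceResult, window: EffectWindow) -> bool:
    """True iff >= 1 significant bin lies inside the window."""
    idx = _window_index(result.geometry, window)
    return bool((result.mask & idx).any())


def best_electrode(masks: list[SignificanceResult], window: EffectWindow):
    """Electrode with the highest cross-subject sum of significant bins.

    Returns ``(electrode, per_subject_counts)`` where the counts are the
    significant-bin counts of each subject at that electrode within the
    window.  Ties break toward the first electrode in channel order (with
    a logged notice); an all-zero map falls back to the first electrode of
    the window's set, flagged "no effect".
    """
    if not masks:
        raise ConfigurationError("need at least one subject")
    geo = masks[0].geometry
    idx = _window_index(geo, window)
    electrodes = resolve_electrodes(window.electrodes, geo.channels)
    per_subject = np.stack([(r.mask & idx).sum(axis=tuple(
        range(r.mask.ndim - 1))) for r in masks])   # subject x channel
    totals = per_subject.sum(axis=0)
    candidates = [i for i, c in enumerate(geo.channels) if c in electrodes]
    best = max(candidates, key=lambda i: (totals[i], -i))
    ties = [geo.channels[i] for i in candidates
            if totals[i] == totals[best] and i != best]
    if ties:
        logger.info("best_electrode %s: tie between %s and %s, keeping "
                    "channel-order first", window.name, geo.channels[best], ties)
    if totals[best] == 0:
        logger.info("best_electrode %s: no significant bins (no effect)",
                    window.name)
        best = candidates[0]
    return geo.channels[best], per_subject[:, best]


def binomial_group_test(s: int, n: int = 18, p0: float = 0.05) -> float:
    """Exact one-sided upper-tail binomial probability P(X >= s | n, p0)."""
    if not 0 < p0 < 1:
        raise ConfigurationError("p0 must lie in (0, 1)")
    if not 0 <= s <= n:
        raise ConfigurationError(f"successes s={s} outside [0, {n}]")
    return float(stats.binom.sf(s - 1, n, p0))


def default_effect_windows() -> tuple[EffectWindow, ...]:
    """The study's summary-table effect windows.

    Five ERP windows (t-s and d-s at Fz in the P300 range; t-d over all
    electrodes in three ranges covering N1+P3a/b, P3a/b alone and the late
    negative component) and eight time-frequency windows (delta-theta
    200-600 ms over frontal/parietal/central; alpha 500-1000 ms over
    parieto-occipital; two single-instant minor effects at 700 and 900 ms
    widened by one STFT hop, 32 ms, on each side; and the full-range t-d
    window).
    """
    hop = 32.0
    return (
        EffectWindow("t-s Fz 0.3-0.4 s", "standard-target", 300, 400, "Fz"),
        EffectWindow("d-s Fz 0.3-0.4 s", "standard-distractor", 300, 400, "Fz"),
        EffectWindow("t-d all 0.15-0.45 s", "target-distractor", 150, 450, "all"),
        EffectWindow("t-d all 0.2-0.4 s", "target-distractor", 200, 400, "all"),
        EffectWindow("t-d all 0.45-0.75 s", "target-distractor", 450, 750, "all"),
        EffectWindow("t-s fpc 0.2-0.6 s 1-5 Hz", "standard-target", 200, 600,
                     "fpc", band_hz=(1, 5), domain="tfr"),
        EffectWindow("d-s fpc 0.2-0.6 s 1-5 Hz", "standard-distractor", 200, 600,
                     "fpc", band_hz=(1, 5), domain="tfr"),
        EffectWindow("t-s po 0.5-1 s 7-9 Hz", "standard-target", 500, 1000,
                     "po", band_hz=(7, 9), domain="tfr"),
        EffectWindow("d-s po 0.5-1 s 7-9 Hz", "standard-distractor", 500, 1000,
                     "po", band_hz=(7, 9), domain="tfr"),
        EffectWindow("t-s all 0.7 s 1-2 Hz", "standard-target", 700 - hop,
                     700 + hop, "all", band_hz=(1, 2), domain="tfr"),
        EffectWindow("t-s all 0.9 s 7-13 Hz", "standard-target", 900 - hop,
                     900 + hop, "all", band_hz=(7, 13), domain="tfr"),
        EffectWindow("d-s all 0.9 s 7-13 Hz", "standard-distractor", 900 - hop,
                     900 + hop, "all", band_hz=(7, 13), domain="tfr"),
        EffectWindow("t-d all 0-1 s allHz", "target-distractor", 0, 1000,
                     "all", band_hz=None, domain="tfr"),
    )


def build_effect_table(results: dict[str, dict[str, SignificanceResult]],
                       windows=None, p0: float = 0.05,
                       domains: tuple[str, ...] = ("erp", "tfr")) -> EffectTable:
    """Subject x window effect matrix with binomial group p-values.

    ``results`` maps subject id -> domain -> contrast -> result, i.e.
    ``results[subj]["erp"]["standard-target"]``.  Windows whose domain was
    not analysed are skipped.
    """
    windows = tuple(windows) if windows is not None else default_effect_windows()
    subjects = sorted(results)
    n = len(subjects)
    rows = {}
    for w in windows:
        if w.domain not in domains:
            continue
        vals = []
        for subj in subjects:
            domain_results = results[subj].get(w.domain, {})
            if w.contrast not in domain_results:
                raise ConfigurationError(
                    f"window {w.name!r}: contrast {w.contrast!r} missing for "
                    f"subject {subj}"
                )
            vals.append(window_effect(domain_results[w.contrast], w))
        rows[w.name] = vals
    table = pd.DataFrame.from_dict(rows, orient="index", columns=subjects)
    successes = table.sum(axis=1)
    p_vals = successes.map(lambda s: binomial_group_test(int(s), n, p0))
    return EffectTable(table=table, successes=successes, p_binomial=p_vals,
                       n_subjects=n, p0=p0)
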