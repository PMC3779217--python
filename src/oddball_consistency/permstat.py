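"""Single-threshold max-statistic permutation t-tests with FWER control.

For one subject and one pair of conditions, a pooled-variance two-sample
t statistic is computed at every analysis point (time x electrode for
ERPs, time x frequency x electrode for spectrograms).  The pooled trials
are then randomly re-partitioned many times; each permutation contributes
the most negative and the most positive t value of its whole map to two
extreme-value histograms.  Comparing each observed t against the
histogram of the map-wide extreme gives p-values that control the
family-wise error rate across all points without any further correction.
When the number of distinct partitions does not exceed the requested
permutation count the test switches to exact enumeration.

Two tail conventions are provided (see ``PermTestConfig.tail_mode``):
``"per-tail"`` compares each observed t to its own-sign histogram at the
full corrected alpha, ``"split"`` halves alpha across the tails and is
the mode that bounds the overall family-wise rate at the corrected alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np

from .config import ConfigurationError, PermTestConfig

__all__ = ["PointGeometry", "SignificanceResult", "pointwise_t",
           "permutation_null", "permutation_pvalues", "permutation_test",
           "run_contrasts", "CONTRASTS"]

logger = logging.getLogger(__name__)

CONTRASTS: tuple[tuple[str, str], ...] = (
    ("standard", "target"), ("standard", "distractor"), ("target", "distractor"),
)


@dataclass(frozen=True)
class PointGeometry:
    """Axes of an analysis-point map.

    ``freqs_hz`` is None for ERP maps (time x electrode) and a vector for
    spectrogram maps (time x frequency x electrode).
    """

    times_ms: tuple[float, ...]
    channels: tuple[str, ...]
    freqs_hz: tuple[float, ...] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        if self.freqs_hz is None:
            return (len(self.times_ms), len(self.channels))
        return (len(self.times_ms), len(self.freqs_hz), len(self.channels))

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class NullHistograms:
    """Recorded per-permutation map-wide extremes."""

    minima: np.ndarray
    maxima: np.ndarray
    exact: bool
    n_permutations: int

    def __post_init__(self) -> None:
        if len(self.minima) != len(self.maxima):
            raise ConfigurationError("each permutation contributes one min and one max")


@dataclass
class SignificanceResult:
    """Observed t-map, null extremes, p-map and corrected-alpha mask."""

    t_obs: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    null: NullHistograms
    geometry: PointGeometry
    contrast: str
    config: PermTestConfig
    subject_id: str = ""
    n_untestable: int = 0

    @property
    def n_significant(self) -> int:
        return int(self.mask.sum())


def _group_stats(sum_x, sum_x2, n):
    mean = sum_x / n
    ss = sum_x2 - n * mean**2
    return mean, np.maximum(ss, 0.0)


def _t_from_sums(s_a, q_a, n_a, s_b, q_b, n_b):
    """Pooled-variance Student t from per-group sums and sums of squares.

    Points with zero pooled variance are returned as NaN (untestable).
    """
    m_a, ss_a = _group_stats(s_a, q_a, n_a)
    m_b, ss_b = _group_stats(s_b, q_b, n_b)
    sp2 = (ss_a + ss_b) / (n_a + n_b - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m_a - m_b) / denom
    t[~np.isfinite(t)] = np.nan
    return t


def pointwise_t(group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Independent two-sample pooled-variance t at every point.

    Inputs are (n_trials, *points); the output has the point shape.
    All-constant points come back NaN and are excluded downstream.
    """
    n_a, n_b = group_a.shape[0], group_b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ConfigurationError("each group needs at least 2 trials")
    a = group_a.reshape(n_a, -1).astype(float)
    b = group_b.reshape(n_b, -1).astype(float)
    t = _t_from_sums(a.sum(0), (a**2).sum(0), n_a, b.sum(0), (b**2).sum(0), n_b)
    return t.reshape(group_a.shape[1:])


def _selection_matrices(n_total: int, n_a: int, config: PermTestConfig,
                        rng: np.random.Generator):
    """Boolean (m, n_total) selection of group A per permutation."""
    total = comb(n_total, n_a)
    if total <= config.n_permutations:
        logger.info("exact enumeration: %d partitions <= %d requested",
                    total, config.n_permutations)
        sel = np.zeros((total, n_total), dtype=bool)
        for i, idx in enumerate(combinations(range(n_total), n_a)):
            sel[i, list(idx)] = True
        return sel, True
    m = config.n_permutations
    sel = np.zeros((m, n_total), dtype=bool)
    for i in range(m):
        sel[i, rng.permutation(n_total)[:n_a]] = True
    return sel, False


def permutation_null(pooled: np.ndarray, n_a: int, config: PermTestConfig,
                     rng: np.random.Generator | None = None) -> NullHistograms:
    """Map-wide extreme t-values over random (or exhaustive) partitions.

    ``pooled`` is (n_total, *points); each partition assigns ``n_a`` trials
    to group A and the rest to group B, computes the full t-map and records
    its global minimum and maximum (NaN points excluded).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_total = pooled.shape[0]
    if n_a < 2 or n_total - n_a < 2:
        raise ConfigurationError("each group needs at least 2 trials")
    x = pooled.reshape(n_total, -1).astype(float)
    x2 = x**2
    s_tot, q_tot = x.sum(0), x2.sum(0)
    sel, exact = _selection_matrices(n_total, n_a, config, rng)

    minima, maxima = [], []
    chunk = max(1, int(2e7 // max(x.shape[1], 1)))
    for lo in range(0, sel.shape[0], chunk):
        block = sel[lo:lo + chunk].astype(float)
        s_a = block @ x
        q_a = block @ x2
        t = _t_from_sums(s_a, q_a, n_a, s_tot - s_a, q_tot - q_a,
                         n_total - n_a)
        with np.errstate(all="ignore"):
            minima.append(np.nanmin(t, axis=1))
            maxima.append(np.nanmax(t, axis=1))
    return NullHistograms(minima=np.concatenate(minima),
                          maxima=np.concatenate(maxima), exact=exact,
                          n_permutations=sel.shape[0])


def permutation_pvalues(t_obs: np.ndarray, null: NullHistograms,
                        config: PermTestConfig, geometry: PointGeometry,
                        contrast: str = "", subject_id: str = "") -> SignificanceResult:
    """Per-point p-values against the extreme histograms, plus the mask.

    A positive observed t is compared with the recorded maxima (fraction
    >= t), a non-positive t with the recorded minima (fraction <= t).  In
    Monte-Carlo mode the add-one convention p = (b+1)/(m+1) is applied; in
    exact mode p = b/m (the observed partition is itself enumerated).
    The mask thresholds p at the corrected alpha (or half of it per tail
    in ``"split"`` mode); untestable (NaN) points are never significant.
    """
    m = null.n_permutations
    flat = np.asarray(t_obs, dtype=float).ravel()
    testable = np.isfinite(flat)
    n_untestable = int((~testable).sum())
    if n_untestable:
        logger.info("%s: %d untestable (zero-variance) points excluded",
                    contrast or "contrast", n_untestable)

    maxima = np.sort(null.maxima)
    minima = np.sort(null.minima)
    # relative tolerance so the observed partition's own extreme counts as
    # "as extreme" despite float round-off between computation paths
    tol = 1e-9 * (1.0 + np.abs(flat))
    b_pos = m - np.searchsorted(maxima, flat - tol, side="left")  # maxima >= t
    b_neg = np.searchsorted(minima, flat + tol, side="right")     # minima <= t
    b = np.where(flat > 0, b_pos, b_neg)
    if null.exact:
        p = b / m
    else:
        p = (b + 1.0) / (m + 1.0)
    p = np.where(testable, p, 1.0)

    alpha_corr = config.corrected_alpha
    threshold = alpha_corr / 2.0 if config.tail_mode == "split" else alpha_corr
    mask = testable & (p < threshold)
    shape = np.asarray(t_obs).shape
    return SignificanceResult(
        t_obs=np.asarray(t_obs, dtype=float), p=p.reshape(shape),
        mask=mask.reshape(shape), null=null, geometry=geometry,
        contrast=contrast, config=config, subject_id=subject_id,
        n_untestable=n_untestable,
    )


def permutation_test(group_a: np.ndarray, group_b: np.ndarray,
                     config: PermTestConfig, geometry: PointGeometry,
                     contrast: str = "", subject_id: str = "",
                     rng: np.random.Generator | None = None) -> SignificanceResult:
    """Observed t-map, permutation null and p-values in one call."""
    t_obs = pointwise_t(group_a, group_b)
    pooled = np.concatenate([group_a, group_b], axis=0)
    null = permutation_null(pooled, group_a.shape[0], config, rng)
    return permutation_pvalues(t_obs, null, config, geometry, contrast,
                               subject_id)


def run_contrasts(trial_maps: Mapping[str, np.ndarray], geometry: PointGeometry,
                  config: PermTestConfig, subject_id: str = "",
                  contrasts: Sequence[tuple[str, str]] = CONTRASTS,
                  ) -> dict[str, SignificanceResult]:
    """All pairwise condition contrasts at a shared corrected alpha.

    ``trial_maps`` maps condition -> (n_trials, *geometry.shape); the three
    default contrasts share alpha/3.  Applies identically to ERP and
    spectrogram maps.  Each contrast uses an independent seed stream
    derived from (config.seed, contrast index).
    """
    for a, b in contrasts:
        for cond in (a, b):
            if cond not in trial_maps:
                raise ConfigurationError(f"missing condition {cond!r}")
    out = {}
    for k, (a, b) in enumerate(contrasts):
        rng = np.random.default_rng([int(config.seed), 3000 + k])
        label = f"{a}-{b}"
        out[label] = permutation_test(trial_maps[a], trial_maps[b], config,
                                      geometry, contrast=label,
                                      subject_id=subject_id, rng=rng)
        logger.info(
            "%s %s: corrected alpha %.4g, %d permutations%s, %d significant, "
            "%d untestable points", subject_id, label, config.corrected_alpha,
            out[label].null.n_permutations,
            " (exact)" if out[label].null.exact else "",
            out[label].n_significant, out[label].n_untestable,
        )
    return out
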