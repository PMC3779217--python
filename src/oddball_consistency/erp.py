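"""Event-related potential analysis: condition averages, difference waves,
global field potentials and windowed scalp-map tables.

Kept trials are band-pass filtered 1-20 Hz (zero phase, per segment),
truncated to 0-1000 ms post-stimulus and averaged within condition.  The
GFP follows the Lehmann-Skrandies definition: the spatial root-mean-square
of the map about its spatial mean at each time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CONDITIONS, ConfigurationError, FilterSpec
from .preprocess import EpochMask, zero_phase_bandpass
from .simulate import EpochSet

__all__ = ["ERP", "InsufficientDataError", "erp_trial_maps", "erp_pipeline",
           "difference_wave", "gfp", "scalp_map_windows",
           "ERP_FILTER", "truncate_window"]

ERP_FILTER = FilterSpec(low_hz=1.0, high_hz=20.0)


class InsufficientDataError(ValueError):
    """A condition has too few kept trials to average."""


@dataclass
class ERP:
    """A channel x time mean waveform for one condition (microvolts)."""

    data: np.ndarray
    times_ms: np.ndarray
    fs_hz: float
    channel_names: tuple[str, ...]
    condition: str
    n_trials: int

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.channel_names), len(self.times_ms)):
            raise ConfigurationError("ERP shape does not match axes")


def truncate_window(times_ms: np.ndarray, start_ms: float,
                    end_ms: float) -> np.ndarray:
    """Boolean index of samples with start <= t <= end (inclusive)."""
    return (times_ms >= start_ms - 1e-9) & (times_ms <= end_ms + 1e-9)


def erp_trial_maps(epochs: EpochSet, keep_mask: EpochMask | None = None,
                   filter_spec: FilterSpec = ERP_FILTER,
                   window_ms: tuple[float, float] = (0.0, 1000.0)):
    """Filtered, truncated single-trial maps grouped by condition.

    Returns ``(maps, times_ms)`` where ``maps`` maps condition ->
    (n_trials, n_channels, n_times) array of kept trials.  This is the
    common front end of ERP averaging and the ERP permutation statistics.
    """
    filtered = zero_phase_bandpass(epochs, filter_spec)
    sel = truncate_window(filtered.times_ms, *window_ms)
    times = filtered.times_ms[sel]
    keep = (keep_mask.keep if keep_mask is not None
            else np.ones(epochs.n_trials, dtype=bool))
    labels = np.asarray(epochs.labels)
    maps = {}
    for cond in CONDITIONS:
        idx = keep & (labels == cond)
        maps[cond] = filtered.data[idx][:, :, sel]
    return maps, times


def erp_point_maps(epochs: EpochSet, keep_mask: EpochMask | None = None,
                   filter_spec: FilterSpec = ERP_FILTER,
                   window_ms: tuple[float, float] = (0.0, 1000.0)):
    """Trial maps in analysis-point order (n_trials, n_times, n_channels).

    Returns ``(maps, geometry)`` ready for the permutation statistics,
    whose point grids are time-major.
    """
    from .permstat import PointGeometry

    maps, times = erp_trial_maps(epochs, keep_mask, filter_spec, window_ms)
    geometry = PointGeometry(times_ms=tuple(times),
                             channels=tuple(epochs.channel_names))
    return {c: np.ascontiguousarray(m.transpose(0, 2, 1))
            for c, m in maps.items()}, geometry


def erp_pipeline(epochs: EpochSet, keep_mask: EpochMask | None = None,
                 filter_spec: FilterSpec = ERP_FILTER,
                 window_ms: tuple[float, float] = (0.0, 1000.0)) -> dict[str, ERP]:
    """Per-condition ERPs from kept trials (filter, truncate, average)."""
    maps, times = erp_trial_maps(epochs, keep_mask, filter_spec, window_ms)
    out = {}
    for cond, trials in maps.items():
        if trials.shape[0] < 2:
            raise InsufficientDataError(
                f"condition {cond!r} has {trials.shape[0]} kept trials (< 2)"
            )
        out[cond] = ERP(data=trials.mean(axis=0), times_ms=times,
                        fs_hz=epochs.fs_hz, channel_names=epochs.channel_names,
                        condition=cond, n_trials=trials.shape[0])
    return out


def difference_wave(erp_a: ERP, erp_b: ERP) -> ERP:
    """Pointwise a - b with matching axes."""
    if erp_a.data.shape != erp_b.data.shape or \
            not np.allclose(erp_a.times_ms, erp_b.times_ms) or \
            erp_a.channel_names != erp_b.channel_names:
        raise ConfigurationError("difference_wave: axis mismatch")
    return ERP(data=erp_a.data - erp_b.data, times_ms=erp_a.times_ms,
               fs_hz=erp_a.fs_hz, channel_names=erp_a.channel_names,
               condition=f"{erp_a.condition}-{erp_b.condition}",
               n_trials=min(erp_a.n_trials, erp_b.n_trials))


def gfp(difference: ERP) -> np.ndarray:
    """Global field potential: spatial RMS about the spatial mean.

    Zero exactly where the map is spatially uniform; invariant to the sign
    of the difference.
    """
    if len(difference.channel_names) < 2:
        raise ConfigurationError("GFP undefined for a single channel")
    return difference.data.std(axis=0, ddof=0)


def scalp_map_windows(difference: ERP, range_ms: tuple[float, float],
                      step_ms: float = 20.0):
    """Per-window per-electrode time-means of a difference wave.

    Windows tile ``range_ms`` without overlap in ``step_ms`` steps; each
    window is half-open [start, start+step) except the last, which includes
    the range end so the tiling covers the range exactly.  Returns a
    pandas DataFrame (window_start_ms, window_end_ms, electrode, mean_uV).
    """
    import pandas as pd

    t = difference.times_ms
    start, end = range_ms
    if start < t[0] - 1e-9 or end > t[-1] + 1e-9:
        raise ConfigurationError(
            f"scalp-map range {range_ms} exceeds data extent ({t[0]}, {t[-1]})"
        )
    n_win = int(round((end - start) / step_ms))
    if n_win < 1 or abs(start + n_win * step_ms - end) > 1e-6:
        raise ConfigurationError("range must be an integer number of steps")
    rows = []
    for k in range(n_win):
        w0 = start + k * step_ms
        w1 = w0 + step_ms
        last = k == n_win - 1
        sel = (t >= w0 - 1e-9) & ((t <= w1 + 1e-9) if last else (t < w1 - 1e-9))
        means = difference.data[:, sel].mean(axis=1)
        for ch, m in zip(difference.channel_names, means):
            rows.append({"window_start_ms": w0, "window_end_ms": w1,
                         "electrode": ch, "mean_uV": float(m)})
    return pd.DataFrame(rows)
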