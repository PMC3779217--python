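"""Zero-phase band-pass filtering and rule-based artifact rejection.

The filter is an order-4 Butterworth applied forward and backward
(scipy ``sosfiltfilt``), the standard zero-phase equivalent of a
48 dB/oct roll-off.  Artifact inspection applies three amplitude rules per
epoch and channel: a maximal voltage step per sampling point, a maximal
peak-to-peak difference over a 200 ms sliding window, and a minimal
peak-to-peak difference over a 100 ms sliding window (a flatline
detector).  A trial is rejected when any rule fires on any channel; the
rules' exclusion margins are clipped at epoch edges because the unit of
data here is the epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .config import ArtifactCriteria, ConfigurationError, FilterSpec
from .simulate import EpochSet

__all__ = ["EpochMask", "zero_phase_bandpass", "artifact_scan",
           "bandpass_sos", "filter_magnitude_response"]


@dataclass
class EpochMask:
    """Per-trial keep flags plus the rules each rejected trial violated."""

    keep: np.ndarray                      # boolean, one entry per trial
    rules_violated: list[tuple[str, ...]]  # per trial, possibly empty

    def __post_init__(self) -> None:
        if len(self.keep) != len(self.rules_violated):
            raise ConfigurationError("mask length mismatch")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def bandpass_sos(spec: FilterSpec, fs_hz: float) -> np.ndarray:
    spec.validate(fs_hz)
    return signal.butter(spec.order, [spec.low_hz, spec.high_hz],
                         btype="bandpass", fs=fs_hz, output="sos")


def filter_magnitude_response(spec: FilterSpec, fs_hz: float,
                              freqs_hz: np.ndarray) -> np.ndarray:
    """|H(f)| of the zero-phase (forward-backward) filter = |H_fwd|^2."""
    sos = bandpass_sos(spec, fs_hz)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs_hz, dtype=float), fs=fs_hz)
    return np.abs(h) ** 2


def zero_phase_bandpass(epochs: EpochSet, spec: FilterSpec) -> EpochSet:
    """Forward-backward Butterworth band-pass over the time axis.

    Zero phase by construction: a symmetric in-band pulse keeps its peak
    sample.  Each epoch is filtered independently (per segment).
    """
    sos = bandpass_sos(spec, epochs.fs_hz)
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochSet(data=np.ascontiguousarray(filtered), fs_hz=epochs.fs_hz,
                    t0_offset_ms=epochs.t0_offset_ms,
                    channel_names=epochs.channel_names,
                    labels=epochs.labels, subject_id=epochs.subject_id)


def _window_samples(window_ms: float, fs_hz: float) -> int:
    return max(1, int(round(window_ms * fs_hz / 1000.0)))


def _range_in_windows(x: np.ndarray, win: int) -> np.ndarray:
    """Per full sliding window (step 1 sample): max - min along time."""
    if x.shape[-1] < win:
        win = x.shape[-1]
    v = sliding_window_view(x, win, axis=-1)
    return v.max(axis=-1) - v.min(axis=-1)


def artifact_scan(epochs: EpochSet, criteria: ArtifactCriteria) -> EpochMask:
    """Apply the three automatic-inspection rules to every trial.

    A trial is rejected iff, on any channel, (a) any single-sample step
    exceeds ``max_step_uV``, (b) the peak-to-peak range within any
    ``max_diff_window_ms`` window exceeds ``max_diff_uV``, or (c) the
    range within any ``min_diff_window_ms`` window falls below
    ``min_diff_uV``.  Exclusion margins mark surrounding samples; since a
    trial containing any marked sample is rejected, the margins are
    outcome-neutral within an epoch and the rule reduces to the trigger
    itself.  Idempotent and independent across trials.
    """
    n_trials = epochs.n_trials
    keep = np.ones(n_trials, dtype=bool)
    rules: list[tuple[str, ...]] = []
    if n_trials == 0:
        return EpochMask(keep=keep, rules_violated=rules)

    data = epochs.data
    fs = epochs.fs_hz
    step_bad = np.abs(np.diff(data, axis=-1)).max(axis=(1, 2)) > criteria.max_step_uV

    win_max = _window_samples(criteria.max_diff_window_ms, fs)
    win_min = _window_samples(criteria.min_diff_window_ms, fs)
    if data.shape[-1] < max(win_max, win_min):
        raise ConfigurationError("epoch shorter than the largest rule window")
    rng_max = _range_in_windows(data, win_max)     # trial x ch x windows
    rng_min = _range_in_windows(data, win_min)
    maxdiff_bad = rng_max.max(axis=(1, 2)) > criteria.max_diff_uV
    mindiff_bad = rng_min.min(axis=(1, 2)) < criteria.min_diff_uV

    for i in range(n_trials):
        violated = []
        if step_bad[i]:
            violated.append("step")
        if maxdiff_bad[i]:
            violated.append("max_diff")
        if mindiff_bad[i]:
            violated.append("min_diff")
        keep[i] = not violated
        rules.append(tuple(violated))
    return EpochMask(keep=keep, rules_violated=rules)
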