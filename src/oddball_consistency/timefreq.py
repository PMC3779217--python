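"""Per-trial STFT spectrograms with pre-stimulus baseline subtraction.

Each 2.2 s epoch is cut into 128 ms Hamming-windowed subdivisions every
64 ms (first window left-aligned to the epoch start; a bin's timestamp is
its window center).  Magnitude (amplitude, microvolts) is evaluated at the
configured frequency centers — 1, 3, ..., 45 Hz by default — by direct
windowed DFT at those frequencies, which matches a zero-padded transform
read at the same bins.  Per trial, frequency and channel, the mean of the
bins whose centers fall in the -200..0 ms baseline is subtracted, and the
result is truncated to bins centered in 0..1000 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .config import CONDITIONS, ConfigurationError, StftConfig
from .simulate import EpochSet

__all__ = ["Spectrogram", "stft_spectrogram", "baseline_subtract",
           "condition_differences", "tfr_trial_maps", "stft_time_bin_count"]


@dataclass
class Spectrogram:
    """Trial x time-bin x frequency-bin x channel amplitude maps (uV)."""

    amplitudes: np.ndarray
    time_centers_ms: np.ndarray
    freq_centers_hz: np.ndarray
    channel_names: tuple[str, ...]
    labels: tuple[str, ...]
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        exp = (len(self.labels), len(self.time_centers_ms),
               len(self.freq_centers_hz), len(self.channel_names))
        if self.amplitudes.shape != exp:
            raise ConfigurationError(
                f"spectrogram shape {self.amplitudes.shape} != expected {exp}"
            )


def stft_time_bin_count(n_samples: int, fs_hz: float, config: StftConfig) -> int:
    """Closed-form number of full subdivisions that fit the epoch."""
    win = int(round(config.window_ms * fs_hz / 1000.0))
    hop = int(round(config.hop_ms * fs_hz / 1000.0))
    if n_samples < win:
        return 0
    return (n_samples - win) // hop + 1


def stft_spectrogram(epochs: EpochSet, config: StftConfig | None = None) -> Spectrogram:
    """Hamming-windowed STFT amplitude at the configured frequency centers.

    Amplitude is normalised so a unit sinusoid at a bin center yields an
    amplitude of ~1 at that bin (2|X| / sum(w)).
    """
    config = config or StftConfig()
    fs = epochs.fs_hz
    config.validate(fs)
    win = int(round(config.window_ms * fs / 1000.0))
    hop = int(round(config.hop_ms * fs / 1000.0))
    n_samp = epochs.data.shape[-1]
    if n_samp < win:
        raise ConfigurationError("epoch shorter than one STFT subdivision")

    w = get_window(config.window_shape, win, fftbins=True)
    freqs = config.freq_centers_hz()
    n = np.arange(win)
    # direct DFT at arbitrary centers: E[f, n] = exp(-2*pi*i*f*n/fs)
    dft = np.exp(-2j * np.pi * freqs[:, None] * n[None, :] / fs) * w[None, :]

    segs = sliding_window_view(epochs.data, win, axis=-1)[:, :, ::hop, :]
    # segs: trial x ch x bin x win -> amplitudes trial x bin x freq x ch
    spec = np.tensordot(segs, dft.conj().T, axes=([3], [0]))  # t x ch x bin x f
    amps = (2.0 / w.sum()) * np.abs(spec).transpose(0, 2, 3, 1)

    starts = np.arange(segs.shape[2]) * hop
    centers_ms = epochs.t0_offset_ms + (starts + win / 2.0) * 1000.0 / fs
    return Spectrogram(amplitudes=amps, time_centers_ms=centers_ms,
                       freq_centers_hz=freqs,
                       channel_names=epochs.channel_names,
                       labels=epochs.labels)


def baseline_subtract(spec: Spectrogram, config: StftConfig | None = None) -> Spectrogram:
    """Subtract the mean pre-stimulus bin per (trial, frequency, channel).

    Baseline bins are those whose centers lie inside ``config.baseline_ms``
    (inclusive); the output keeps only bins centered inside
    ``config.output_ms``.
    """
    config = config or StftConfig()
    t = spec.time_centers_ms
    base = (t >= config.baseline_ms[0] - 1e-9) & (t <= config.baseline_ms[1] + 1e-9)
    if not base.any():
        raise ConfigurationError(
            f"no STFT bin center falls in the baseline window {config.baseline_ms}"
        )
    out_sel = (t >= config.output_ms[0] - 1e-9) & (t <= config.output_ms[1] + 1e-9)
    baseline = spec.amplitudes[:, base].mean(axis=1, keepdims=True)
    corrected = (spec.amplitudes - baseline)[:, out_sel]
    return Spectrogram(amplitudes=corrected, time_centers_ms=t[out_sel],
                       freq_centers_hz=spec.freq_centers_hz,
                       channel_names=spec.channel_names, labels=spec.labels,
                       baseline_subtracted=True)


def tfr_trial_maps(epochs: EpochSet, keep_mask=None,
                   config: StftConfig | None = None):
    """Baseline-corrected single-trial spectrograms grouped by condition.

    Returns ``(maps, time_centers_ms, freq_centers_hz)`` with ``maps``
    mapping condition -> (n_trials, n_timebins, n_freqs, n_channels); the
    common front end of spectrogram averaging and the TFR permutation
    statistics.  Trials rejected by the artifact scan are excluded first.
    """
    config = config or StftConfig()
    spec = baseline_subtract(stft_spectrogram(epochs, config), config)
    keep = (keep_mask.keep if keep_mask is not None
            else np.ones(len(spec.labels), dtype=bool))
    labels = np.asarray(spec.labels)
    maps = {c: spec.amplitudes[keep & (labels == c)] for c in CONDITIONS}
    return maps, spec.time_centers_ms, spec.freq_centers_hz


CONTRAST_PAIRS: tuple[tuple[str, str], ...] = (
    ("standard", "target"), ("standard", "distractor"), ("target", "distractor"),
)


def condition_differences(maps: dict[str, np.ndarray]):
    """Mean difference spectrograms plus jointly normalised display copies.

    Returns ``(diffs, normalized, bounds)``: ``diffs`` maps "a-b" ->
    unnormalised mean(a) - mean(b) for the three contrasts; ``normalized``
    holds display copies affinely mapped to [0, 1] using one global
    min/max shared by all three; ``bounds`` is that (min, max) pair.
    """
    for cond in ("standard", "target", "distractor"):
        if cond not in maps or maps[cond].shape[0] == 0:
            raise ConfigurationError(f"condition {cond!r} has no kept trials")
    means = {c: maps[c].mean(axis=0) for c in ("standard", "target", "distractor")}
    diffs = {f"{a}-{b}": means[a] - means[b] for a, b in CONTRAST_PAIRS}
    gmin = min(float(d.min()) for d in diffs.values())
    gmax = max(float(d.max()) for d in diffs.values())
    span = gmax - gmin if gmax > gmin else 1.0
    normalized = {k: (d - gmin) / span for k, d in diffs.items()}
    return diffs, normalized, (gmin, gmax)
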