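"""Configuration dataclasses for the oddball consistency pipeline.

All stages are parameterised by small frozen dataclasses so that a run is
fully described by one YAML/JSON document plus a master seed.  The defaults
reproduce the study conditions: 15 scalp channels at 250 Hz, 2.2 s epochs
(-600..+1600 ms), 300 standard / 50 target / 50 distractor trials with each
deviant preceded by 2-7 standards, Butterworth zero-phase filtering, a
128 ms Hamming STFT on a 2 Hz grid, and 1000-permutation max-statistic
tests at a Bonferroni-corrected alpha of 0.05/3.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

DEFAULT_CHANNELS: tuple[str, ...] = (
    "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "P7", "P8", "Fz", "Cz", "Pz",
)

CONDITIONS: tuple[str, ...] = ("standard", "target", "distractor")


class ConfigurationError(ValueError):
    """A configuration violates one of its documented invariants."""


@dataclass(frozen=True)
class ParadigmConfig:
    """Stimulus-sequence and epoching parameters of the active oddball task."""

    n_standard: int = 300
    n_target: int = 50
    n_distractor: int = 50
    min_gap: int = 2
    max_gap: int = 7
    trial_duration_ms: float = 1500.0
    jitter_range_ms: tuple[float, float] = (34.0, 480.0)
    sampling_rate_hz: float = 250.0
    epoch_start_ms: float = -600.0
    epoch_end_ms: float = 1600.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    n_parts: int = 2

    def __post_init__(self) -> None:
        n_dev = self.n_target + self.n_distractor
        if self.min_gap > self.max_gap or self.min_gap < 0:
            raise ConfigurationError("gap bounds must satisfy 0 <= min_gap <= max_gap")
        if n_dev * self.min_gap > self.n_standard:
            raise ConfigurationError(
                f"too few standards: {self.n_standard} < "
                f"{n_dev} deviants * min_gap {self.min_gap}"
            )
        if self.n_standard > n_dev * self.max_gap:
            raise ConfigurationError(
                f"too many standards: {self.n_standard} > "
                f"{n_dev} deviants * max_gap {self.max_gap}"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("duplicate channel names")
        if self.epoch_end_ms <= self.epoch_start_ms:
            raise ConfigurationError("epoch window is empty")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_samples(self) -> int:
        span = self.epoch_end_ms - self.epoch_start_ms
        return int(round(span * self.sampling_rate_hz / 1000.0))

    @property
    def epoch_times_ms(self):
        import numpy as np

        dt = 1000.0 / self.sampling_rate_hz
        return self.epoch_start_ms + dt * np.arange(self.n_samples)


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass.

    ``rolloff_db_per_oct`` of 48 corresponds to an order-4 filter applied
    forward and backward (8 effective poles).  The recorder's quoted time
    constant (0.1592 s) merely restates the 1 Hz high-pass corner
    (1/(2*pi*1 Hz)) and is carried as metadata only.
    """

    low_hz: float = 1.0
    high_hz: float = 48.0
    design: str = "butterworth"
    rolloff_db_per_oct: int = 48
    zero_phase: bool = True
    order: int = 4

    def validate(self, fs_hz: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ConfigurationError("band edges must satisfy 0 < low < high")
        if self.high_hz >= fs_hz / 2:
            raise ConfigurationError(
                f"high edge {self.high_hz} Hz >= Nyquist {fs_hz / 2} Hz"
            )


@dataclass(frozen=True)
class ArtifactCriteria:
    """Automatic rejection rules applied per epoch (thresholds in microvolts)."""

    max_step_uV: float = 50.0
    step_margin_ms: float = 100.0
    max_diff_uV: float = 200.0
    max_diff_window_ms: float = 200.0
    min_diff_uV: float = 0.5
    min_diff_window_ms: float = 100.0
    min_diff_margin_ms: float = 500.0

    def __post_init__(self) -> None:
        for name in ("max_step_uV", "max_diff_uV", "min_diff_uV"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass(frozen=True)
class StftConfig:
    """Short-time Fourier transform layout.

    128 ms windows at 250 Hz hold 32 samples; the 2 Hz grid with centers at
    odd frequencies (1, 3, ..., 45 Hz) is obtained by evaluating the
    windowed DFT directly at those centers (equivalent to zero-padding each
    subdivision to one second).  A bin's timestamp is its window center and
    a bin belongs to the baseline/output range if its center lies inside.
    """

    window_ms: float = 128.0
    hop_ms: float = 64.0
    window_shape: str = "hamming"
    freq_start_hz: float = 1.0
    freq_step_hz: float = 2.0
    freq_stop_hz: float = 45.0
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    output_ms: tuple[float, float] = (0.0, 1000.0)

    def validate(self, fs_hz: float) -> None:
        if self.hop_ms > self.window_ms:
            raise ConfigurationError("hop must not exceed window length")
        if self.freq_stop_hz >= fs_hz / 2:
            raise ConfigurationError("freq_stop must be below Nyquist")
        if self.baseline_ms[1] > 0:
            raise ConfigurationError("baseline must precede the stimulus")

    def freq_centers_hz(self):
        import numpy as np

        return np.arange(self.freq_start_hz, self.freq_stop_hz + 1e-9,
                         self.freq_step_hz)


@dataclass(frozen=True)
class PermTestConfig:
    """Max-statistic permutation test parameters.

    ``tail_mode`` selects how the two extreme histograms are used:

    - ``"per-tail"``: each observed t is compared against its own-sign
      histogram at the full corrected alpha (the historical procedure this
      pipeline mirrors; controls each tail at alpha_corr, so the overall
      family-wise rate can reach ~2*alpha_corr);
    - ``"split"``: alpha_corr is split across the tails (alpha_corr/2 each),
      giving an overall family-wise rate of alpha_corr.
    """

    n_permutations: int = 1000
    alpha: float = 0.05
    n_contrasts_correction: int = 3
    seed: int = 0
    tail_mode: str = "per-tail"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.tail_mode not in ("per-tail", "split"):
            raise ConfigurationError("tail_mode must be 'per-tail' or 'split'")

    @property
    def corrected_alpha(self) -> float:
        return self.alpha / self.n_contrasts_correction


def _as_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    return dict(obj)


def config_hash(*objs) -> str:
    """Stable sha256 over the canonical JSON of one or more config objects."""
    payload = json.dumps([_as_dict(o) for o in objs], sort_keys=True,
                         default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError("config document must be a mapping")
    return doc


def paradigm_from_dict(doc: dict) -> ParadigmConfig:
    kwargs = dict(doc)
    for key in ("jitter_range_ms",):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "channel_names" in kwargs:
        kwargs["channel_names"] = tuple(kwargs["channel_names"])
    return ParadigmConfig(**kwargs)
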