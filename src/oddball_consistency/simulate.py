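"""Synthetic multi-subject oddball EEG generator.

The generator emulates the active auditory oddball paradigm: a frequent
standard tone and two rare deviants (a target the subject silently counts
and a distractor to be ignored), each deviant preceded by 2-7 standards.
Epochs are synthesized directly (no continuous recording): each trial is
spatially correlated 1/f background noise plus an ongoing alpha rhythm,
condition-gated Gaussian-kernel ERP components (N1, P3a, P3b, late
negative component) and condition-gated band-limited power modulations
(delta-theta increase, alpha decrease with an optional inverted-response
subpopulation).  Between-subject heterogeneity — amplitude/latency scaling,
whether the subject expresses a target-vs-distractor difference at all, and
the sign of the alpha response — is drawn per subject from one master seed
so that any single stage can be reproduced in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .config import CONDITIONS, ConfigurationError, ParadigmConfig

__all__ = [
    "ComponentSpec",
    "OscillationSpec",
    "EffectConfig",
    "SubjectProfile",
    "StimulusSequence",
    "EpochSet",
    "generate_sequence",
    "draw_subject_profile",
    "synthesize_epochs",
    "inject_artifacts",
    "default_components",
    "default_oscillations",
    "simulate_subject",
    "simulate_cohort",
]

# Approximate 10-20 scalp positions on the unit disc (x: left-right,
# y: posterior-anterior); used to build smooth topographies and the
# spatial noise-mixing matrix.
CHANNEL_XY: dict[str, tuple[float, float]] = {
    "F3": (-0.35, 0.55), "F4": (0.35, 0.55),
    "C3": (-0.45, 0.00), "C4": (0.45, 0.00),
    "P3": (-0.35, -0.55), "P4": (0.35, -0.55),
    "O1": (-0.25, -0.90), "O2": (0.25, -0.90),
    "F7": (-0.70, 0.60), "F8": (0.70, 0.60),
    "P7": (-0.70, -0.60), "P8": (0.70, -0.60),
    "Fz": (0.00, 0.55), "Cz": (0.00, 0.00), "Pz": (0.00, -0.55),
}


def gaussian_topography(channels: Sequence[str], center_xy: tuple[float, float],
                        sigma: float = 0.55) -> np.ndarray:
    """Smooth per-channel weights in (0, 1] peaking at ``center_xy``."""
    xy = np.array([CHANNEL_XY[c] for c in channels])
    d2 = ((xy - np.asarray(center_xy)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * sigma**2))


@dataclass(frozen=True)
class ComponentSpec:
    """One stimulus-locked ERP component modelled as a Gaussian kernel.

    ``condition_gains`` multiplies the peak amplitude per condition;
    ``td_gated`` marks components whose target/distractor gain difference
    is expressed only by subjects drawn with the target-vs-distractor
    effect (non-expressing subjects receive the mean of the two gains for
    both deviants, preserving the deviant-vs-standard response).
    """

    name: str
    latency_ms: float
    width_ms: float
    amplitude_uV: float
    topography: np.ndarray
    condition_gains: Mapping[str, float]
    latency_jitter_sd_ms: float = 20.0
    subject_amp_sd: float = 0.3
    subject_lat_sd_ms: float = 15.0
    td_gated: bool = False

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ConfigurationError(f"component {self.name}: width_ms must be > 0")


@dataclass(frozen=True)
class OscillationSpec:
    """One condition-gated event-related band-power modulation.

    ``power_change`` maps condition -> signed relative power change within
    ``window_ms`` (+1 doubles band power, -0.5 halves it).  Increases are
    realised by adding independent band-limited noise of matched RMS
    (``base_amplitude_uV`` sets the reference band RMS); decreases by
    attenuating the background's band content under a raised-cosine
    envelope.  With probability ``sign_flip_prob`` a subject expresses the
    inverted response (the sign of every condition's change flips).
    """

    name: str
    band_hz: tuple[float, float]
    window_ms: tuple[float, float]
    power_change: Mapping[str, float]
    topography: np.ndarray
    base_amplitude_uV: float = 2.0
    envelope: str = "raised-cosine"
    sign_flip_prob: float = 0.0

    def __post_init__(self) -> None:
        low, high = self.band_hz
        if not 0 < low < high:
            raise ConfigurationError(f"oscillation {self.name}: bad band {self.band_hz}")
        if not 0.0 <= self.sign_flip_prob <= 1.0:
            raise ConfigurationError("sign_flip_prob must lie in [0, 1]")


@dataclass(frozen=True)
class EffectConfig:
    """Cohort-level effect structure and noise model."""

    components: tuple[ComponentSpec, ...]
    oscillations: tuple[OscillationSpec, ...]
    prevalence_td: float = 8.0 / 18.0
    noise_level_uV: float = 8.0
    noise_subject_sd: float = 0.2       # lognormal sigma on noise level
    alpha_fraction: float = 0.5         # ongoing-alpha RMS relative to noise
    spatial_mix_sigma: float = 0.45     # channel-mixing kernel width

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence_td <= 1.0:
            raise ConfigurationError("prevalence_td must lie in [0, 1]")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject draws; fully determined by (master seed, subject index)."""

    subject_id: str
    subject_index: int
    component_amp: Mapping[str, float]      # multiplicative, ~lognormal
    component_lat_ms: Mapping[str, float]   # additive latency offset
    oscillation_sign: Mapping[str, float]   # +1 or -1
    expresses_td_effect: bool
    noise_level_uV: float
    rng_seed: int


@dataclass(frozen=True)
class StimulusSequence:
    """Ordered stimulus stream: (condition, onset ms, part index) triples."""

    events: tuple[tuple[str, float, int], ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.events)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CONDITIONS}
        for lab, _, _ in self.events:
            out[lab] += 1
        return out

    def deviant_gaps(self) -> list[int]:
        """Standards preceding each deviant, counted within its part."""
        gaps, run = [], 0
        part = None
        for lab, _, p in self.events:
            if p != part:
                part, run = p, 0
            if lab == "standard":
                run += 1
            else:
                gaps.append(run)
                run = 0
        return gaps


@dataclass
class EpochSet:
    """One subject's epoched trials: (trial, channel, time) in microvolts."""

    data: np.ndarray
    fs_hz: float
    t0_offset_ms: float
    channel_names: tuple[str, ...]
    labels: tuple[str, ...]
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ConfigurationError("EpochSet.data must be trial x channel x time")
        if self.data.shape[0] != len(self.labels):
            raise ConfigurationError("label count does not match trial count")
        if self.data.shape[1] != len(self.channel_names):
            raise ConfigurationError("channel count does not match channel names")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.fs_hz
        return self.t0_offset_ms + dt * np.arange(self.data.shape[2])

    def condition_index(self, label: str) -> np.ndarray:
        return np.array([lab == label for lab in self.labels])


# ---------------------------------------------------------------------------
# stimulus sequence
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _composition_counts(k: int, total: int, lo: int, hi: int) -> tuple:
    """count[j][s] = number of ways to write s as a sum of j values in [lo, hi].

    Exact integer dynamic programme; feasible sums per row are bounded by
    [j*lo, j*hi] so the table stays small for paradigm-sized inputs.
    """
    rows: list[dict[int, int]] = [dict() for _ in range(k + 1)]
    rows[0][0] = 1
    for j in range(1, k + 1):
        row: dict[int, int] = {}
        for s_prev, cnt in rows[j - 1].items():
            for g in range(lo, hi + 1):
                s = s_prev + g
                if s <= total:
                    row[s] = row.get(s, 0) + cnt
        rows[j] = row
    return tuple(rows)


def _sample_gaps(k: int, total: int, lo: int, hi: int,
                 rng: np.random.Generator) -> list[int]:
    """Draw uniformly among all k-part compositions of ``total`` in [lo, hi]."""
    rows = _composition_counts(k, total, lo, hi)
    if rows[k].get(total, 0) == 0:
        raise ConfigurationError(
            f"cannot partition {total} standards into {k} gaps within "
            f"[{lo}, {hi}]: need {k * lo} <= {total} <= {k * hi}"
        )
    gaps, s = [], total
    for j in range(k, 0, -1):
        weights = np.array(
            [float(rows[j - 1].get(s - g, 0)) for g in range(lo, hi + 1)]
        )
        g = lo + int(rng.choice(len(weights), p=weights / weights.sum()))
        gaps.append(g)
        s -= g
    assert s == 0
    return gaps


def _split_counts(n: int, n_parts: int) -> list[int]:
    base, rem = divmod(n, n_parts)
    return [base + (1 if i < rem else 0) for i in range(n_parts)]


def generate_sequence(config: ParadigmConfig, seed: int) -> StimulusSequence:
    """Generate a stimulus sequence obeying the paradigm constraints.

    The session is split into ``n_parts`` parts presenting equal stimulus
    counts; within each part every deviant is preceded by ``min_gap`` to
    ``max_gap`` standards and the gaps absorb all of the part's standards.
    Gap vectors are drawn exactly uniformly over all feasible assignments;
    the target/distractor identity order is a uniform random interleaving.
    """
    rng = np.random.default_rng(seed)
    std_parts = _split_counts(config.n_standard, config.n_parts)
    tgt_parts = _split_counts(config.n_target, config.n_parts)
    dst_parts = _split_counts(config.n_distractor, config.n_parts)

    events: list[tuple[str, float, int]] = []
    t = 0.0
    jit_lo, jit_hi = config.jitter_range_ms
    for part in range(config.n_parts):
        n_dev = tgt_parts[part] + dst_parts[part]
        if n_dev == 0:
            if std_parts[part]:
                raise ConfigurationError(
                    f"part {part}: standards present but no deviants to anchor gaps"
                )
            continue
        gaps = _sample_gaps(n_dev, std_parts[part], config.min_gap,
                            config.max_gap, rng)
        identities = ["target"] * tgt_parts[part] + ["distractor"] * dst_parts[part]
        rng.shuffle(identities)
        for gap, dev in zip(gaps, identities):
            for _ in range(gap):
                events.append(("standard", t, part))
                t += config.trial_duration_ms + rng.uniform(jit_lo, jit_hi)
            events.append((dev, t, part))
            t += config.trial_duration_ms + rng.uniform(jit_lo, jit_hi)
    return StimulusSequence(events=tuple(events))


# ---------------------------------------------------------------------------
# subject profiles
# ---------------------------------------------------------------------------

def draw_subject_profile(config: ParadigmConfig, effects: EffectConfig,
                         master_seed: int, subject_index: int) -> SubjectProfile:
    """Draw one subject's heterogeneity parameters, reproducibly.

    The RNG is keyed on (master seed, subject index), so profiles are
    independent of the order in which subjects are drawn.
    """
    rng = np.random.default_rng([int(master_seed), 1000 + int(subject_index)])
    comp_amp = {}
    comp_lat = {}
    for comp in effects.components:
        comp_amp[comp.name] = float(
            np.exp(rng.normal(0.0, comp.subject_amp_sd))
        )
        comp_lat[comp.name] = float(rng.normal(0.0, comp.subject_lat_sd_ms))
    osc_sign = {
        osc.name: (-1.0 if rng.random() < osc.sign_flip_prob else 1.0)
        for osc in effects.oscillations
    }
    expresses = bool(rng.random() < effects.prevalence_td)
    noise = float(
        effects.noise_level_uV * np.exp(rng.normal(0.0, effects.noise_subject_sd))
    )
    return SubjectProfile(
        subject_id=f"S{subject_index + 1:02d}",
        subject_index=subject_index,
        component_amp=comp_amp,
        component_lat_ms=comp_lat,
        oscillation_sign=osc_sign,
        expresses_td_effect=expresses,
        noise_level_uV=noise,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# epoch synthesis
# ---------------------------------------------------------------------------

def _mixing_matrix(channels: Sequence[str], sigma: float) -> np.ndarray:
    """Row-normalised smooth channel-mixing kernel (spatial correlation)."""
    xy = np.array([CHANNEL_XY[c] for c in channels])
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    mix = np.exp(-d2 / (2.0 * sigma**2))
    # unit row L2 norm keeps per-channel variance at the source variance
    return mix / np.linalg.norm(mix, axis=1, keepdims=True)


def _shaped_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                  fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f amplitude profile per channel."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    shape = 1.0 / np.maximum(freqs, 1.0)
    shape[0] = 0.0  # no DC
    spec *= shape
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _bandpass_fft(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Brick-wall zero-phase band filter along the last axis (per trial)."""
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return np.fft.irfft(spec * mask, n=x.shape[-1], axis=-1)


def _raised_cosine(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    on, off = window_ms
    env = np.zeros_like(times_ms)
    inside = (times_ms >= on) & (times_ms <= off)
    phase = (times_ms[inside] - on) / (off - on)
    env[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return env


def _effective_gains(spec: ComponentSpec, expresses_td: bool) -> dict[str, float]:
    gains = dict(spec.condition_gains)
    if spec.td_gated and not expresses_td:
        mean_dev = 0.5 * (gains.get("target", 0.0) + gains.get("distractor", 0.0))
        gains["target"] = mean_dev
        gains["distractor"] = mean_dev
    return gains


def synthesize_epochs(sequence: StimulusSequence, profile: SubjectProfile,
                      config: ParadigmConfig,
                      components: Sequence[ComponentSpec],
                      oscillations: Sequence[OscillationSpec],
                      effects: EffectConfig | None = None) -> EpochSet:
    """Synthesize one subject's epoched EEG from the signal model.

    Each trial is background noise (spatially mixed 1/f broadband plus an
    ongoing 10 Hz rhythm with random phase and amplitude), plus
    condition-gated Gaussian ERP components and band-limited power
    modulations.  Deterministic given the profile's seed.
    """
    n_ch = config.n_channels
    for comp in components:
        if len(np.asarray(comp.topography)) != n_ch:
            raise ConfigurationError(
                f"component {comp.name}: topography length != {n_ch} channels"
            )
    for osc in oscillations:
        if len(np.asarray(osc.topography)) != n_ch:
            raise ConfigurationError(
                f"oscillation {osc.name}: topography length != {n_ch} channels"
            )

    fs = config.sampling_rate_hz
    times = config.epoch_times_ms
    n_samp = config.n_samples
    labels = sequence.labels
    n_trials = len(labels)
    rng = np.random.default_rng(profile.rng_seed)

    alpha_frac = effects.alpha_fraction if effects is not None else 0.5
    mix_sigma = effects.spatial_mix_sigma if effects is not None else 0.45
    mix = _mixing_matrix(config.channel_names, mix_sigma)
    alpha_topo = gaussian_topography(config.channel_names, (0.0, -0.7), 0.6)
    noise_uV = profile.noise_level_uV

    data = np.zeros((n_trials, n_ch, n_samp))
    t_sec = times / 1000.0

    for i, label in enumerate(labels):
        # -- background ----------------------------------------------------
        if noise_uV > 0:
            bg = noise_uV * (mix @ _shaped_noise(rng, n_ch, n_samp, fs))
            phase = rng.uniform(0.0, 2.0 * np.pi)
            a_amp = alpha_frac * noise_uV * math.sqrt(2.0) \
                * float(np.exp(rng.normal(0.0, 0.3)))
            bg = bg + np.outer(alpha_topo, a_amp * np.sin(
                2.0 * np.pi * 10.0 * t_sec + phase))
        else:
            bg = np.zeros((n_ch, n_samp))

        # -- oscillatory modulations ---------------------------------------
        for osc in oscillations:
            delta = float(osc.power_change.get(label, 0.0))
            delta *= profile.oscillation_sign.get(osc.name, 1.0)
            if delta == 0.0:
                continue
            env = _raised_cosine(times, osc.window_ms)
            topo = np.asarray(osc.topography, dtype=float)
            if delta > 0:
                # additive independent band-limited noise of matched power
                src = _bandpass_fft(rng.standard_normal(n_samp), fs, osc.band_hz)
                src_rms = src.std() or 1.0
                add_rms = osc.base_amplitude_uV * math.sqrt(delta)
                bg = bg + np.outer(topo, env * (add_rms / src_rms) * src)
            else:
                # attenuate the background's band content inside the window
                band = _bandpass_fft(bg, fs, osc.band_hz)
                gain = np.sqrt(np.clip(1.0 + delta * topo, 0.0, None)) - 1.0
                bg = bg + gain[:, None] * env[None, :] * band

        # -- transient components ------------------------------------------
        for comp in components:
            gains = _effective_gains(comp, profile.expresses_td_effect)
            gain = float(gains.get(label, 0.0))
            jitter = (rng.normal(0.0, comp.latency_jitter_sd_ms)
                      if comp.latency_jitter_sd_ms > 0 else 0.0)
            if gain == 0.0:
                continue
            amp = comp.amplitude_uV * profile.component_amp.get(comp.name, 1.0) * gain
            lat = comp.latency_ms + profile.component_lat_ms.get(comp.name, 0.0) + jitter
            kernel = np.exp(-0.5 * ((times - lat) / comp.width_ms) ** 2)
            bg = bg + np.outer(np.asarray(comp.topography, dtype=float),
                               amp * kernel)

        data[i] = bg

    return EpochSet(data=data, fs_hz=fs, t0_offset_ms=config.epoch_start_ms,
                    channel_names=tuple(config.channel_names), labels=labels,
                    subject_id=profile.subject_id)


# ---------------------------------------------------------------------------
# artifact injection (fixtures for the rejection rules)
# ---------------------------------------------------------------------------

def inject_artifacts(epochs: EpochSet, artifact_plan: Sequence[tuple[int, str, float]],
                     seed: int = 0) -> EpochSet:
    """Return a copy with planned artifacts written into listed trials.

    Plan entries are (trial index, type, magnitude in microvolts) with type
    one of ``step`` (single-sample voltage step), ``drift`` (smooth
    excursion of the given peak-to-peak size within a 200 ms window) or
    ``flatline`` (the whole trial set constant).  Each archetype violates
    exactly one automatic-inspection rule at study-default thresholds.
    """
    rng = np.random.default_rng(seed)
    data = epochs.data.copy()
    n_trials, n_ch, n_samp = data.shape
    fs = epochs.fs_hz
    for trial, kind, magnitude in artifact_plan:
        if not 0 <= trial < n_trials:
            raise IndexError(f"artifact plan trial {trial} out of range")
        ch = int(rng.integers(0, n_ch))
        if kind == "step":
            pos = int(rng.integers(n_samp // 4, 3 * n_samp // 4))
            data[trial, ch, pos:] += magnitude
        elif kind == "drift":
            width = int(round(0.2 * fs))  # 200 ms excursion
            pos = int(rng.integers(n_samp // 4, 3 * n_samp // 4 - width))
            bump = 0.5 * magnitude * (1.0 - np.cos(
                2.0 * np.pi * np.arange(width) / width))
            data[trial, ch, pos:pos + width] += bump
        elif kind == "flatline":
            data[trial] = magnitude
        else:
            raise ConfigurationError(f"unknown artifact type {kind!r}")
    return EpochSet(data=data, fs_hz=epochs.fs_hz,
                    t0_offset_ms=epochs.t0_offset_ms,
                    channel_names=epochs.channel_names, labels=epochs.labels,
                    subject_id=epochs.subject_id)


# ---------------------------------------------------------------------------
# study defaults
# ---------------------------------------------------------------------------

def default_components(channels: Sequence[str] | None = None,
                       amplitude_scale: float = 1.0) -> tuple[ComponentSpec, ...]:
    """Study-default ERP components.

    Amplitudes and latencies follow the canonical auditory-oddball
    morphology: an N1 around 100 ms for every tone (slightly larger for
    deviants), a fronto-central P3a and a parietal P3b for deviants only
    (their target/distractor asymmetry is expressed only by subjects who
    carry the target-vs-distractor effect), and a fronto-central late
    negative component around 450-750 ms, larger for distractors.
    ``amplitude_scale`` scales every component for high-SNR recovery runs.
    """
    from .config import DEFAULT_CHANNELS

    ch = tuple(channels) if channels is not None else DEFAULT_CHANNELS
    s = amplitude_scale
    return (
        ComponentSpec(
            name="N1", latency_ms=100.0, width_ms=22.0, amplitude_uV=-4.0 * s,
            topography=gaussian_topography(ch, (0.0, 0.25), 0.8),
            condition_gains={"standard": 1.0, "target": 1.3, "distractor": 1.3},
            latency_jitter_sd_ms=8.0, subject_amp_sd=0.3, subject_lat_sd_ms=8.0,
        ),
        ComponentSpec(
            name="P3a", latency_ms=300.0, width_ms=50.0, amplitude_uV=8.0 * s,
            topography=gaussian_topography(ch, (0.0, 0.35), 0.65),
            condition_gains={"standard": 0.0, "target": 0.65, "distractor": 1.0},
            latency_jitter_sd_ms=22.0, subject_amp_sd=0.3, subject_lat_sd_ms=18.0,
            td_gated=True,
        ),
        ComponentSpec(
            name="P3b", latency_ms=360.0, width_ms=60.0, amplitude_uV=9.0 * s,
            topography=gaussian_topography(ch, (0.0, -0.55), 0.6),
            condition_gains={"standard": 0.0, "target": 1.0, "distractor": 0.4},
            latency_jitter_sd_ms=25.0, subject_amp_sd=0.3, subject_lat_sd_ms=20.0,
            td_gated=True,
        ),
        ComponentSpec(
            name="LNC", latency_ms=600.0, width_ms=80.0, amplitude_uV=-4.0 * s,
            topography=gaussian_topography(ch, (0.0, 0.15), 0.8),
            condition_gains={"standard": 0.0, "target": 0.45, "distractor": 1.0},
            latency_jitter_sd_ms=30.0, subject_amp_sd=0.35, subject_lat_sd_ms=25.0,
            td_gated=True,
        ),
    )


def default_oscillations(channels: Sequence[str] | None = None,
                         power_scale: float = 1.0,
                         alpha_flip_prob: float = 2.0 / 18.0) -> tuple[OscillationSpec, ...]:
    """Study-default event-related band-power modulations.

    Deviants carry a delta-theta power increase (~200-600 ms, frontal/
    central/parietal) and an alpha power decrease (~300-1000 ms,
    parieto-occipital); a configurable fraction of subjects expresses the
    inverted alpha response.  Target and distractor changes are equal, so
    the time-frequency target-vs-distractor contrast is null by default.
    """
    from .config import DEFAULT_CHANNELS

    ch = tuple(channels) if channels is not None else DEFAULT_CHANNELS
    s = power_scale
    return (
        OscillationSpec(
            name="delta_theta", band_hz=(1.0, 5.0), window_ms=(200.0, 600.0),
            power_change={"standard": 0.0, "target": 1.5 * s, "distractor": 1.5 * s},
            topography=gaussian_topography(ch, (0.0, 0.0), 0.9),
            base_amplitude_uV=4.0,
        ),
        OscillationSpec(
            name="alpha", band_hz=(7.0, 12.0), window_ms=(300.0, 1000.0),
            power_change={"standard": 0.0, "target": -0.6 * s, "distractor": -0.6 * s},
            topography=gaussian_topography(ch, (0.0, -0.7), 0.6),
            base_amplitude_uV=3.0,
            sign_flip_prob=alpha_flip_prob,
        ),
    )


def default_effects(channels: Sequence[str] | None = None,
                    prevalence_td: float = 8.0 / 18.0,
                    noise_level_uV: float = 8.0,
                    amplitude_scale: float = 1.0,
                    power_scale: float = 1.0,
                    alpha_flip_prob: float = 2.0 / 18.0) -> EffectConfig:
    """Bundle default components/oscillations into an :class:`EffectConfig`."""
    return EffectConfig(
        components=default_components(channels, amplitude_scale),
        oscillations=default_oscillations(channels, power_scale, alpha_flip_prob),
        prevalence_td=prevalence_td,
        noise_level_uV=noise_level_uV,
    )


def simulate_subject(config: ParadigmConfig, effects: EffectConfig,
                     master_seed: int, subject_index: int,
                     profile: SubjectProfile | None = None,
                     ) -> tuple[SubjectProfile, EpochSet]:
    """Draw a profile, generate a sequence and synthesize one subject.

    A pre-built ``profile`` (e.g. with a stratified effect assignment)
    overrides the default per-subject draw.
    """
    if profile is None:
        profile = draw_subject_profile(config, effects, master_seed, subject_index)
    seq_seed = int(np.random.default_rng(
        [int(master_seed), 2000 + int(subject_index)]).integers(0, 2**31 - 1))
    sequence = generate_sequence(config, seq_seed)
    epochs = synthesize_epochs(sequence, profile, config,
                               effects.components, effects.oscillations, effects)
    return profile, epochs


def simulate_cohort(config: ParadigmConfig, effects: EffectConfig,
                    master_seed: int, n_subjects: int = 18):
    """Yield (profile, epochs) for each subject of a cohort."""
    for idx in range(n_subjects):
        yield simulate_subject(config, effects, master_seed, idx)
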