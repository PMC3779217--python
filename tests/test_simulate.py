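"""Stimulus-sequence generation and synthetic-EEG signal model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oddball_consistency.config import ConfigurationError, ParadigmConfig
from oddball_consistency.simulate import (ComponentSpec, EffectConfig,
                                          default_effects,
                                          draw_subject_profile,
                                          gaussian_topography,
                                          generate_sequence, inject_artifacts,
                                          simulate_subject, synthesize_epochs)


class TestSequence:
    def test_default_session_counts_and_gap_bounds(self, paradigm):
        """Every seed yields 300/50/50 stimuli with deviant gaps in [2, 7]."""
        for seed in range(50):
            seq = generate_sequence(paradigm, seed)
            assert seq.counts() == {"standard": 300, "target": 50,
                                    "distractor": 50}
            gaps = seq.deviant_gaps()
            assert len(gaps) == 100
            assert sum(gaps) == 300
            assert all(2 <= g <= 7 for g in gaps)

    def test_parts_present_equal_stimulus_counts(self, paradigm):
        seq = generate_sequence(paradigm, 3)
        parts = np.array([p for _, _, p in seq.events])
        assert (parts == 0).sum() == (parts == 1).sum() == 200

    def test_onsets_strictly_increasing_with_jitter(self, paradigm):
        seq = generate_sequence(paradigm, 5)
        onsets = np.array([t for _, t, _ in seq.events])
        gaps = np.diff(onsets)
        lo = paradigm.trial_duration_ms + paradigm.jitter_range_ms[0]
        hi = paradigm.trial_duration_ms + paradigm.jitter_range_ms[1]
        assert np.all(gaps >= lo - 1e-9) and np.all(gaps <= hi + 1e-9)

    def test_single_feasible_assignment_is_forced(self):
        cfg = ParadigmConfig(n_standard=2, n_target=1, n_distractor=0,
                             n_parts=1)
        for seed in (0, 1, 2):
            assert generate_sequence(cfg, seed).labels == \
                ("standard", "standard", "target")

    def test_infeasible_totals_raise_naming_bound(self):
        with pytest.raises(ConfigurationError, match="min_gap"):
            ParadigmConfig(n_standard=3, n_target=2, n_distractor=0,
                           n_parts=1)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_invariants_hold_for_arbitrary_feasible_configs(self, data):
        """Totals, gap bounds and gap sums hold for any feasible paradigm."""
        min_gap = data.draw(st.integers(0, 3), label="min_gap")
        max_gap = data.draw(st.integers(min_gap + 1, min_gap + 5),
                            label="max_gap")
        n_target = data.draw(st.integers(0, 5), label="n_target")
        n_distractor = data.draw(st.integers(1 - min(n_target, 1), 5),
                                 label="n_distractor")
        n_dev = n_target + n_distractor
        n_standard = data.draw(
            st.integers(n_dev * min_gap, n_dev * max_gap), label="n_standard")
        seed = data.draw(st.integers(0, 2**16), label="seed")
        cfg = ParadigmConfig(n_standard=n_standard, n_target=n_target,
                             n_distractor=n_distractor, min_gap=min_gap,
                             max_gap=max_gap, n_parts=1)
        seq = generate_sequence(cfg, seed)
        assert seq.counts() == {"standard": n_standard, "target": n_target,
                                "distractor": n_distractor}
        gaps = seq.deviant_gaps()
        assert len(gaps) == n_dev and sum(gaps) == n_standard
        assert all(min_gap <= g <= max_gap for g in gaps)

    def test_deterministic_given_seed(self, paradigm):
        assert generate_sequence(paradigm, 11).events == \
            generate_sequence(paradigm, 11).events

    def test_gap_distribution_uniform_over_compositions(self):
        """Tiny case: 2 gaps summing to 5 in [2,3] has exactly two
        compositions (2,3) and (3,2); both should appear about equally."""
        cfg = ParadigmConfig(n_standard=5, n_target=2, n_distractor=0,
                             min_gap=2, max_gap=3, n_parts=1)
        seen = {(2, 3): 0, (3, 2): 0}
        for seed in range(400):
            seen[tuple(generate_sequence(cfg, seed).deviant_gaps())] += 1
        assert seen[(2, 3)] + seen[(3, 2)] == 400
        # binomial(400, .5): 3 sigma = 30
        assert abs(seen[(2, 3)] - 200) < 60


class TestProfiles:
    def test_degenerate_prevalence(self, paradigm):
        always = default_effects(prevalence_td=1.0)
        never = default_effects(prevalence_td=0.0)
        for i in range(10):
            assert draw_subject_profile(paradigm, always, 0, i).expresses_td_effect
            assert not draw_subject_profile(paradigm, never, 0, i).expresses_td_effect

    def test_profile_determinism(self, paradigm):
        eff = default_effects()
        a = draw_subject_profile(paradigm, eff, 42, 3)
        b = draw_subject_profile(paradigm, eff, 42, 3)
        assert a == b

    def test_expressing_count_matches_binomial_mean(self, paradigm):
        """Monte-Carlo mean of expressing-subject counts ~ n*pi."""
        pi = 8.0 / 18.0
        eff = default_effects(prevalence_td=pi)
        n, n_rep = 18, 200
        counts = [
            sum(draw_subject_profile(paradigm, eff, seed, i).expresses_td_effect
                for i in range(n))
            for seed in range(n_rep)
        ]
        se_mean = np.sqrt(n * pi * (1 - pi) / n_rep)
        assert abs(np.mean(counts) - n * pi) < 3 * se_mean


def _single_component_effects(channels, **kwargs):
    defaults = dict(
        name="probe", latency_ms=300.0, width_ms=40.0, amplitude_uV=10.0,
        topography=gaussian_topography(channels, (0.0, 0.0), 0.7),
        condition_gains={"standard": 0.0, "target": 1.0, "distractor": 0.0},
        latency_jitter_sd_ms=0.0, subject_amp_sd=0.0, subject_lat_sd_ms=0.0,
    )
    defaults.update(kwargs)
    comp = ComponentSpec(**defaults)
    return EffectConfig(components=(comp,), oscillations=(),
                        noise_level_uV=0.0, noise_subject_sd=0.0,
                        prevalence_td=1.0), comp


class TestSynthesis:
    def test_noise_free_component_peaks_exactly(self, paradigm):
        """Without noise or jitter the target mean peaks at the component
        latency with amplitude 10 uV * topography weight; standards are 0."""
        effects, comp = _single_component_effects(paradigm.channel_names)
        profile = draw_subject_profile(paradigm, effects, 0, 0)
        seq = generate_sequence(paradigm, 0)
        ep = synthesize_epochs(seq, profile, paradigm, effects.components,
                               effects.oscillations, effects)
        tgt = ep.data[ep.condition_index("target")]
        std = ep.data[ep.condition_index("standard")]
        assert np.all(std == 0.0)
        mean = tgt.mean(axis=0)
        peak_idx = np.abs(mean).max(axis=0).argmax()
        assert ep.times_ms[peak_idx] == pytest.approx(300.0)
        np.testing.assert_allclose(mean[:, peak_idx],
                                   10.0 * comp.topography, rtol=1e-10)

    def test_latency_jitter_recovered_from_peaks(self, paradigm):
        """Trial-level peak-latency SD reproduces the jitter SD within 15%."""
        sigma = 20.0
        effects, comp = _single_component_effects(
            paradigm.channel_names, latency_jitter_sd_ms=sigma,
            condition_gains={"standard": 1.0, "target": 1.0, "distractor": 1.0})
        profile = draw_subject_profile(paradigm, effects, 1, 0)
        seq = generate_sequence(paradigm, 1)
        ep = synthesize_epochs(seq, profile, paradigm, effects.components,
                               effects.oscillations, effects)
        ch = int(np.argmax(comp.topography))
        peak_ms = ep.times_ms[ep.data[:, ch, :].argmax(axis=1)]
        assert abs(np.std(peak_ms) - sigma) < 0.15 * sigma

    def test_bit_identical_under_same_profile(self, paradigm):
        effects = default_effects()
        profile = draw_subject_profile(paradigm, effects, 2, 0)
        seq = generate_sequence(paradigm, 2)
        a = synthesize_epochs(seq, profile, paradigm, effects.components,
                              effects.oscillations, effects)
        b = synthesize_epochs(seq, profile, paradigm, effects.components,
                              effects.oscillations, effects)
        assert np.array_equal(a.data, b.data)

    def test_topography_length_mismatch_raises(self, paradigm):
        effects, comp = _single_component_effects(paradigm.channel_names[:4])
        profile = draw_subject_profile(paradigm, effects, 0, 0)
        seq = generate_sequence(paradigm, 0)
        with pytest.raises(ConfigurationError, match="topography"):
            synthesize_epochs(seq, profile, paradigm, effects.components,
                              (), effects)

    def test_amplitudes_in_plausible_microvolt_range(self, clean_subject):
        _, ep = clean_subject
        rms = ep.data.std()
        assert 2.0 < rms < 50.0


class TestArtifacts:
    def test_empty_plan_is_identity(self, clean_subject):
        _, ep = clean_subject
        out = inject_artifacts(ep, [], seed=0)
        assert np.array_equal(out.data, ep.data)

    def test_planned_trials_violate_exactly_their_rule(self, paradigm):
        from oddball_consistency.config import ArtifactCriteria
        from oddball_consistency.preprocess import artifact_scan

        effects = default_effects(noise_level_uV=2.0)
        _, ep = simulate_subject(paradigm, effects, 3, 0)
        plan = [(3, "step", 60.0), (5, "flatline", 0.0), (8, "drift", 260.0)]
        out = inject_artifacts(ep, plan, seed=1)
        mask = artifact_scan(out, ArtifactCriteria())
        assert "step" in mask.rules_violated[3]
        assert "min_diff" in mask.rules_violated[5]
        assert "max_diff" in mask.rules_violated[8]
        untouched = [i for i in range(ep.n_trials) if i not in (3, 5, 8)]
        assert np.array_equal(out.data[untouched], ep.data[untouched])

    def test_out_of_range_trial_raises(self, clean_subject):
        _, ep = clean_subject
        with pytest.raises(IndexError):
            inject_artifacts(ep, [(ep.n_trials, "step", 60.0)])
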