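"""Subject-count maps, effect windows, best electrodes and binomial tests."""

import math

import numpy as np
import pytest

from oddball_consistency.config import ConfigurationError, PermTestConfig
from oddball_consistency.consistency import (ELECTRODE_GROUPS, EffectWindow,
                                             best_electrode,
                                             binomial_group_test,
                                             build_effect_table,
                                             count_subjects,
                                             default_effect_windows,
                                             window_effect)
from oddball_consistency.permstat import (NullHistograms, PointGeometry,
                                          SignificanceResult)

CHANNELS = ("F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
            "F7", "F8", "P7", "P8", "Fz", "Cz", "Pz")


def _result(mask, geometry, contrast="target-distractor", subject="S01"):
    mask = np.asarray(mask, dtype=bool)
    return SignificanceResult(
        t_obs=np.where(mask, 5.0, 0.0), p=np.where(mask, 0.001, 0.9),
        mask=mask, null=NullHistograms(minima=np.zeros(10),
                                       maxima=np.zeros(10), exact=False,
                                       n_permutations=10),
        geometry=geometry, contrast=contrast, config=PermTestConfig(),
        subject_id=subject)


@pytest.fixture
def erp_geometry():
    times = tuple(np.arange(0.0, 1004.0, 4.0))
    return PointGeometry(times_ms=times, channels=CHANNELS)


@pytest.fixture
def tfr_geometry():
    times = tuple(np.arange(40.0, 1001.0, 64.0))
    freqs = tuple(np.arange(1.0, 46.0, 2.0))
    return PointGeometry(times_ms=times, channels=CHANNELS, freqs_hz=freqs)


class TestCountSubjects:
    def test_all_empty_masks_give_zero_map(self, erp_geometry):
        masks = [_result(np.zeros(erp_geometry.shape), erp_geometry,
                         subject=f"S{i}") for i in range(4)]
        assert count_subjects(masks).sum() == 0

    def test_single_fully_significant_subject_gives_ones(self, erp_geometry):
        masks = [_result(np.ones(erp_geometry.shape), erp_geometry)]
        masks += [_result(np.zeros(erp_geometry.shape), erp_geometry)
                  for _ in range(3)]
        assert np.all(count_subjects(masks) == 1)

    def test_random_masks_match_brute_force_sum(self, erp_geometry):
        rng = np.random.default_rng(0)
        raw = [rng.random(erp_geometry.shape) < 0.1 for _ in range(5)]
        counts = count_subjects([_result(m, erp_geometry) for m in raw])
        expected = sum(m.astype(int) for m in raw)
        np.testing.assert_array_equal(counts, expected)
        # conservation: total count equals the sum of per-subject bins
        assert counts.sum() == sum(m.sum() for m in raw)

    def test_geometry_mismatch_raises(self, erp_geometry, tfr_geometry):
        with pytest.raises(ConfigurationError):
            count_subjects([_result(np.zeros(erp_geometry.shape), erp_geometry),
                            _result(np.zeros(tfr_geometry.shape), tfr_geometry)])


class TestWindowEffect:
    def test_hit_inside_window(self, erp_geometry):
        mask = np.zeros(erp_geometry.shape, dtype=bool)
        t_idx = list(erp_geometry.times_ms).index(352.0)
        mask[t_idx, CHANNELS.index("Cz")] = True
        res = _result(mask, erp_geometry)
        assert window_effect(res, EffectWindow("w", "target-distractor",
                                               300, 400, "all"))
        assert not window_effect(res, EffectWindow("w", "target-distractor",
                                                   450, 750, "all"))

    def test_boundaries_inclusive_both_ends(self, erp_geometry):
        mask = np.zeros(erp_geometry.shape, dtype=bool)
        t_idx = list(erp_geometry.times_ms).index(400.0)
        mask[t_idx, CHANNELS.index("Fz")] = True
        res = _result(mask, erp_geometry)
        assert window_effect(res, EffectWindow("w", "c", 300, 400, "Fz"))
        assert window_effect(res, EffectWindow("w", "c", 400, 500, "Fz"))

    def test_monotone_under_window_enlargement(self, erp_geometry):
        rng = np.random.default_rng(1)
        mask = rng.random(erp_geometry.shape) < 0.02
        res = _result(mask, erp_geometry)
        for lo, hi in ((300, 400), (200, 500), (100, 800), (0, 1000)):
            small = window_effect(res, EffectWindow("w", "c", lo + 50,
                                                    hi - 50, "all"))
            big = window_effect(res, EffectWindow("w", "c", lo, hi, "all"))
            assert big or not small

    def test_band_restriction_in_tfr_geometry(self, tfr_geometry):
        mask = np.zeros(tfr_geometry.shape, dtype=bool)
        f_idx = list(tfr_geometry.freqs_hz).index(3.0)
        mask[2, f_idx, CHANNELS.index("Fz")] = True
        res = _result(mask, tfr_geometry)
        w_in = EffectWindow("w", "c", 0, 1000, "fpc", band_hz=(1, 5),
                            domain="tfr")
        w_out = EffectWindow("w", "c", 0, 1000, "fpc", band_hz=(7, 9),
                             domain="tfr")
        assert window_effect(res, w_in) and not window_effect(res, w_out)

    def test_unknown_electrode_set_raises(self, erp_geometry):
        res = _result(np.zeros(erp_geometry.shape), erp_geometry)
        with pytest.raises(ConfigurationError):
            window_effect(res, EffectWindow("w", "c", 0, 100, "nope"))


class TestBestElectrode:
    def test_only_significant_electrode_wins(self, erp_geometry):
        mask = np.zeros(erp_geometry.shape, dtype=bool)
        mask[10:20, CHANNELS.index("Fz")] = True
        best, counts = best_electrode([_result(mask, erp_geometry)],
                                      EffectWindow("w", "c", 0, 1000, "all"))
        assert best == "Fz"
        assert counts[0] == 10

    def test_tie_breaks_to_channel_order(self, erp_geometry):
        mask = np.zeros(erp_geometry.shape, dtype=bool)
        mask[5, CHANNELS.index("Cz")] = True
        mask[5, CHANNELS.index("F3")] = True
        best, _ = best_electrode([_result(mask, erp_geometry)],
                                 EffectWindow("w", "c", 0, 1000, "all"))
        assert best == "F3"  # earlier in channel order

    def test_matches_brute_force_argmax(self, erp_geometry):
        rng = np.random.default_rng(2)
        raw = [rng.random(erp_geometry.shape) < 0.05 for _ in range(4)]
        window = EffectWindow("w", "c", 200, 600, "all")
        best, _ = best_electrode([_result(m, erp_geometry) for m in raw],
                                 EffectWindow("w", "c", 200, 600, "all"))
        times = np.asarray(erp_geometry.times_ms)
        t_sel = (times >= 200) & (times <= 600)
        sums = sum(m[t_sel].sum(axis=0) for m in raw)
        assert best == CHANNELS[int(np.argmax(sums))]


class TestBinomial:
    def test_single_success_of_18_rounds_to_printed_value(self):
        assert round(binomial_group_test(1, 18, 0.05), 2) == 0.60

    def test_zero_successes_is_certain(self):
        assert binomial_group_test(0, 18, 0.05) == pytest.approx(1.0)

    def test_all_successes_closed_form(self):
        assert binomial_group_test(18, 18, 0.05) == pytest.approx(0.05**18,
                                                                  rel=1e-12)

    def test_agrees_with_cumulative_sum_oracle_for_all_s(self):
        n, p0 = 18, 0.05
        for s in range(n + 1):
            oracle = sum(math.comb(n, k) * p0**k * (1 - p0) ** (n - k)
                         for k in range(s, n + 1))
            assert binomial_group_test(s, n, p0) == pytest.approx(
                oracle, abs=1e-12)

    def test_invalid_successes_raise(self):
        with pytest.raises(ConfigurationError):
            binomial_group_test(19, 18, 0.05)


class TestEffectTable:
    def _cohort_results(self, erp_geometry, tfr_geometry, n=4, seed=3):
        rng = np.random.default_rng(seed)
        results = {}
        for i in range(n):
            subj = f"S{i + 1:02d}"
            results[subj] = {"erp": {}, "tfr": {}}
            for a, b in (("standard", "target"), ("standard", "distractor"),
                         ("target", "distractor")):
                contrast = f"{a}-{b}"
                results[subj]["erp"][contrast] = _result(
                    rng.random(erp_geometry.shape) < 0.01, erp_geometry,
                    contrast, subj)
                results[subj]["tfr"][contrast] = _result(
                    rng.random(tfr_geometry.shape) < 0.01, tfr_geometry,
                    contrast, subj)
        return results

    def test_thirteen_default_windows(self):
        assert len(default_effect_windows()) == 13
        domains = {w.domain for w in default_effect_windows()}
        assert domains == {"erp", "tfr"}

    def test_success_counts_equal_column_sums(self, erp_geometry,
                                              tfr_geometry):
        results = self._cohort_results(erp_geometry, tfr_geometry)
        table = build_effect_table(results)
        for name, row in table.table.iterrows():
            assert table.successes[name] == row.sum()
            assert table.p_binomial[name] == pytest.approx(
                binomial_group_test(int(row.sum()), 4, 0.05))

    def test_erp_only_table_skips_tfr_windows(self, erp_geometry,
                                              tfr_geometry):
        results = self._cohort_results(erp_geometry, tfr_geometry)
        for subj in results:
            results[subj].pop("tfr")
        table = build_effect_table(results, domains=("erp",))
        assert len(table.table) == 5
        assert all("Hz" not in name for name in table.table.index)

    def test_display_uses_x_marks(self, erp_geometry, tfr_geometry):
        results = self._cohort_results(erp_geometry, tfr_geometry)
        disp = build_effect_table(results).display()
        marks = disp.drop(columns=["s", "p"]).to_numpy().ravel()
        assert set(marks) <= {"x", ""}


def test_electrode_groups_follow_ten_twenty_nomenclature():
    assert set(ELECTRODE_GROUPS["fpc"]) == {
        "F3", "F4", "F7", "F8", "Fz", "C3", "C4", "Cz",
        "P3", "P4", "P7", "P8", "Pz"}
    assert set(ELECTRODE_GROUPS["po"]) == {
        "P3", "P4", "P7", "P8", "Pz", "O1", "O2"}
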