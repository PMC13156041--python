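import numpy as np
import pytest

from ecdg import classifier as cls
from ecdg.environments import FAMILIAR, NOVEL, cue_displacement
from ecdg.placefields import PlaceField
from ecdg.remapping import pearson


def bump_map(peaks, n=80, width=2.0):
    lam = np.zeros(n)
    x = np.arange(n)
    for p in peaks:
        lam += np.exp(-0.5 * ((x - p) / width) ** 2)
    return lam


def pf(start, end):
    peak = (start + end) // 2
    return PlaceField(start_bin=start, end_bin=end, peak_bin=peak,
                      width_bins=end - start + 1, in_out_ratio=10.0,
                      transient_occupancy_fraction=0.5, bootstrap_p=0.01)


def profile(fam_peaks, nov_peaks, run_maps=None):
    fields = {FAMILIAR: [pf(p - 2, p + 2) for p in fam_peaks],
              NOVEL: [pf(p - 2, p + 2) for p in nov_peaks]}
    maps = {FAMILIAR: bump_map(fam_peaks), NOVEL: bump_map(nov_peaks)}
    rm = run_maps or {FAMILIAR: np.tile(maps[FAMILIAR], (15, 1)),
                      NOVEL: np.tile(maps[NOVEL], (15, 1))}
    return cls.UnitProfile(unit_id=0, active=True, fields=fields,
                           maps=maps, run_maps=rm)


class TestLaggedXcorr:
    def test_identical_maps_peak_at_zero(self):
        m = bump_map([40])
        lags, rs = cls.lagged_map_xcorr(m, m, 0.05)
        k = np.nanargmax(rs)
        assert lags[k] == 0.0 and rs[k] == pytest.approx(1.0)

    def test_shift_by_20_bins_peaks_at_one_meter(self):
        fam = bump_map([30])
        nov = np.roll(fam, 20)
        lag, r = cls.peak_lag(fam, nov, 0.05)
        assert lag == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        fam, nov = rng.random(80), rng.random(80)
        lags, rs = cls.lagged_map_xcorr(fam, nov, 0.05)
        for lag, r in zip(lags, rs):
            shifted = np.roll(nov, -int(round(lag / 0.05)))
            assert r == pytest.approx(pearson(fam, shifted), abs=1e-12)


class TestWindowGeometry:
    def test_stimulus_window_is_8_bins_from_cue_bin(self, openfield_pair):
        fam, nov = openfield_pair
        # odor at 0.5 m -> bin 10; 40 cm after onset = bins 10..17
        assert cls.stimulus_window_bins(fam, "odor").tolist() == list(
            range(10, 18))
        assert cls.stimulus_window_bins(nov, "odor").tolist() == list(
            range(30, 38))

    def test_object_window_is_12_bins_starting_3_before(self,
                                                        openfield_pair):
        fam, _ = openfield_pair
        # object1 at 1.0 m -> bin 20; window = bins 17..28
        assert cls.object_window_bins(fam, "object1").tolist() == list(
            range(17, 29))

    def test_object_window_clipped_at_track_end(self, openfield_pair):
        _, nov = openfield_pair
        # object2 at 3.7 m -> bin 74; window clipped at bin 79
        assert cls.object_window_bins(nov, "object2").tolist() == list(
            range(71, 80))

    @pytest.mark.parametrize("kind,d,expected", [
        ("odor", 1.0, (0.7, 1.3)),
        ("reward", -1.0, (-1.3, -0.7)),
        ("sound", -2.0, (-2.4, -1.6)),
        ("object1", 1.0, (0.8, 1.2)),
        ("object2", 2.0, (1.7, 2.3)),
        ("object3", -3.0, (-3.4, -2.6)),
    ])
    def test_offset_windows_follow_displacement_sign(self, kind, d,
                                                     expected):
        assert cls.offset_window(kind, d) == expected

    def test_lag_window_membership_is_circular(self):
        # a +3.0-m displacement appears as a -1.0-m circular lag
        assert cls.lag_in_window(-1.0, (2.6, 3.4), 4.0)
        assert cls.lag_in_window(3.0, (2.6, 3.4), 4.0)
        assert not cls.lag_in_window(1.5, (0.7, 1.3), 4.0)
        assert cls.lag_in_window(-2.0, (-2.4, -1.6), 4.0)
        assert cls.lag_in_window(2.0, (-2.4, -1.6), 4.0)  # -2 == +2 mod 4


class TestChecks:
    def test_generalizing_identical_tuned_maps(self):
        assert cls.check_generalizing(profile([40], [40]))

    def test_generalizing_needs_fields_in_both(self):
        p = profile([40], [40])
        p.fields[NOVEL] = []
        assert not cls.check_generalizing(p)

    def test_odor_unit_matches_stated_windows(self, openfield_pair):
        fam, nov = openfield_pair
        # odor familiar bin 10, novel bin 30 (displacement +1.0 m);
        # field 20 cm after the odor in both contexts
        p = profile([14], [34])
        ok, lag, r = cls.check_stimulus(p, openfield_pair, "odor")
        assert ok
        assert lag == pytest.approx(1.0)
        assert r >= 0.6

    def test_odor_field_in_one_context_only_fails(self, openfield_pair):
        p = profile([14], [60])
        ok, _, _ = cls.check_stimulus(p, openfield_pair, "odor")
        assert not ok

    def test_lag_outside_stimulus_window_fails(self, openfield_pair):
        # peaks inside the odor windows of both contexts (bins 17 and 30)
        # but the implied lag of +0.65 m falls outside [0.7, 1.3]
        p = profile([17], [30])
        ok, lag, _ = cls.check_stimulus(p, openfield_pair, "odor")
        assert not ok
        assert lag == pytest.approx(0.65)

    def test_single_object_locked_to_displaced_object(self, openfield_pair):
        fam, nov = openfield_pair
        # object2: familiar bin 34, novel bin 74, displacement +2.0 m
        p = profile([35], [75])
        ok, kind, lag, r = cls.check_single_object(p, openfield_pair)
        assert ok and kind == "object2"
        # a +2.0-m displacement on the 4-m circular track may be reported
        # as the equivalent -2.0-m lag
        assert cls.lag_in_window(lag, (1.7, 2.3), 4.0)

    def test_multi_object_same_set_in_both_contexts(self, openfield_pair):
        fam, nov = openfield_pair
        fam_peaks = [fam.position_to_bin(fam.positions(k)[0]) + 1
                     for k in ("object1", "object3")]
        nov_peaks = [nov.position_to_bin(nov.positions(k)[0]) + 1
                     for k in ("object1", "object3")]
        p = profile(fam_peaks, nov_peaks)
        ok, objs = cls.check_multi_object(p, openfield_pair)
        assert ok and objs == ("object1", "object3")

    def test_multi_object_requires_same_objects(self, openfield_pair):
        fam, nov = openfield_pair
        fam_peaks = [fam.position_to_bin(fam.positions(k)[0]) + 1
                     for k in ("object1", "object3")]
        nov_peaks = [nov.position_to_bin(nov.positions(k)[0]) + 1
                     for k in ("object1", "object4")]
        ok, _ = cls.check_multi_object(profile(fam_peaks, nov_peaks),
                                       openfield_pair)
        assert not ok

    def test_grid_criteria_direct_evaluation(self):
        # four evenly spaced 5-bin fields, W = 0.25 m on L = 4 m:
        # 8 in/out transitions > L/(5W) = 3.2
        peaks = [10, 30, 50, 70]
        lam = bump_map(peaks, width=1.5)
        fields = [pf(p - 2, p + 2) for p in peaks]
        ok, m = cls.check_grid_like(lam, fields, 4.0, 0.05)
        assert ok
        assert m["transitions"] == 8
        assert m["n_fields"] == 4

    def test_single_field_is_not_grid(self):
        lam = bump_map([40], width=1.5)
        ok, _ = cls.check_grid_like(lam, [pf(38, 42)], 4.0, 0.05)
        assert not ok

    def test_two_narrow_fields_fail_transition_count(self):
        # two 3-bin fields: W = 0.15 m needs more than L/(5W) = 5.33
        # transitions, but two isolated fields produce only 4
        peaks = [20, 60]
        lam = bump_map(peaks, width=1.0)
        fields = [pf(p - 1, p + 1) for p in peaks]
        ok, m = cls.check_grid_like(lam, fields, 4.0, 0.05)
        assert not ok
        assert m["transitions"] == 4
        assert m["transitions"] <= 4.0 / (5 * 0.15)


class TestClassifyOrder:
    def test_generalizing_wins_over_odor(self, openfield_pair):
        fam, nov = openfield_pair
        # identical maps peaked in the familiar odor window in both
        # contexts: satisfies generalization, which is checked first
        p = profile([12], [12])
        c = cls.classify_unit(p, openfield_pair)
        assert c.label == "generalizing"

    def test_place_label_for_remapping_tuned_unit(self, openfield_pair):
        p = profile([25], [61])
        c = cls.classify_unit(p, openfield_pair)
        assert c.label == "place"

    def test_nonspatial_when_no_fields_anywhere(self, openfield_pair):
        p = profile([], [])
        c = cls.classify_unit(p, openfield_pair)
        assert c.label == "nonspatial"

    def test_conjunctive_odor_plus_object(self, openfield_pair):
        fam, nov = openfield_pair
        fam_peaks = [12, fam.position_to_bin(fam.positions("object3")[0]) + 1]
        nov_peaks = [32, nov.position_to_bin(nov.positions("object3")[0]) + 1]
        p = profile(fam_peaks, nov_peaks)
        c = cls.classify_unit(p, openfield_pair)
        conj = cls.check_conjunctive(p, openfield_pair, c.label)
        assert conj == ("object3", "odor")

    def test_conjunctive_requires_both_contexts(self, openfield_pair):
        fam, nov = openfield_pair
        p = profile([12, fam.position_to_bin(
            fam.positions("object3")[0]) + 1], [32])
        assert cls.check_conjunctive(p, openfield_pair, "place") is None

    def test_multi_object_excluded_from_conjunctive(self, openfield_pair):
        fam, nov = openfield_pair
        fam_peaks = [fam.position_to_bin(fam.positions(k)[0]) + 1
                     for k in ("object1", "object3")]
        nov_peaks = [nov.position_to_bin(nov.positions(k)[0]) + 1
                     for k in ("object1", "object3")]
        p = profile(fam_peaks, nov_peaks)
        assert cls.check_conjunctive(p, openfield_pair,
                                     "multi_object") is None
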