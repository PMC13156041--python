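import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecdg.environments import FAMILIAR, NOVEL
from ecdg.metrics import (
    ActivityMap, activity_difference_score, activity_map, bin_track,
    lick_ratio, reward_zone_bins, si_shuffle_test, spatial_information,
    speed_metrics, transient_rate_and_active,
)
from ecdg.synthetic import render_fluorescence, simulate_units
from ecdg.transients import process_traces


def _uniform_map(lam):
    lam = np.asarray(lam, dtype=float)
    n = lam.size
    return ActivityMap(lambda_=lam, p=np.full(n, 1 / n),
                       occupancy_s=np.ones(n),
                       visited=np.ones(n, bool), bin_size_m=0.05)


def _si_loop(lam, p, base=2.0):
    lbar = float(np.sum(p * lam))
    total = 0.0
    for li, pi in zip(lam, p):
        if li > 0:
            total += pi * li * np.log(li / lbar)
    return total / np.log(base)


class TestBinning:
    def test_default_track_gives_80_bins(self):
        assert bin_track(4.0, 0.05).size - 1 == 80

    def test_shorter_track(self):
        assert bin_track(1.0, 0.05).size - 1 == 20

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError):
            bin_track(4.0, 0.03)


class TestActivityMap:
    def test_constant_activity_gives_flat_map(self, short_track,
                                              openfield_pair):
        fam, _ = openfield_pair
        m = activity_map(np.full(short_track.n_frames, 2.5), short_track,
                         fam, context=FAMILIAR)
        assert np.allclose(m.lambda_[m.visited], 2.5)
        assert m.p[m.visited].sum() == pytest.approx(1.0)

    def test_all_slow_frames_give_empty_map(self, short_track,
                                            openfield_pair):
        fam, _ = openfield_pair
        m = activity_map(np.ones(short_track.n_frames), short_track, fam,
                         context=FAMILIAR, speed_min_cm_s=1e9)
        assert m.empty

    def test_place_unit_peak_recovered_within_one_bin(self, default_track,
                                                      openfield_pair):
        units = simulate_units({"place": 1.0}, 1, openfield_pair, seed=8)
        raw = render_fluorescence(units, default_track, seed=8)
        traces, _ = process_traces(raw.fluorescence,
                                   default_track.frame_rate_hz)
        fam = openfield_pair[0]
        m = activity_map(traces[0].masked_dff, default_track, fam,
                         context=FAMILIAR)
        from ecdg.synthetic import expressed_field_peak_bin
        true_bin = expressed_field_peak_bin(units[0], raw.event_frames[0],
                                            default_track, fam, FAMILIAR)
        assert abs(int(np.argmax(m.smoothed)) - true_bin) <= 1


class TestSpatialInformation:
    def test_uniform_map_has_zero_information(self):
        si = spatial_information(_uniform_map(np.full(80, 1.3)))
        assert si == pytest.approx(0.0, abs=1e-12)

    def test_single_active_bin_uniform_occupancy(self):
        lam = np.zeros(80)
        lam[17] = 1.0
        si = spatial_information(_uniform_map(lam))
        assert si == pytest.approx(np.log2(80) / 80)

    def test_vectorized_si_matches_loop_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(1000):
            lam = rng.random(80) * rng.choice([0.1, 1.0, 10.0])
            lam[rng.random(80) < 0.3] = 0.0
            p = rng.random(80)
            p /= p.sum()
            amap = ActivityMap(lambda_=lam, p=p, occupancy_s=p,
                               visited=np.ones(80, bool), bin_size_m=0.05)
            if amap.lambda_bar <= 0:
                continue
            assert spatial_information(amap) == pytest.approx(
                _si_loop(lam, p), abs=1e-12)

    def test_si_scales_linearly_with_activity(self):
        rng = np.random.default_rng(11)
        lam = rng.random(80)
        p = np.full(80, 1 / 80)
        base = spatial_information(_uniform_map(lam))
        for c in (0.5, 3.0, 17.0):
            amap = _uniform_map(c * lam)
            assert spatial_information(amap) == pytest.approx(c * base)

    def test_silent_map_undefined(self):
        assert np.isnan(spatial_information(_uniform_map(np.zeros(80))))


class TestSiShuffle:
    def test_strong_place_unit_is_significant(self, default_track,
                                              openfield_pair):
        fam = openfield_pair[0]
        units = simulate_units({"place": 1.0}, 1, openfield_pair, seed=12)
        raw = render_fluorescence(units, default_track, seed=12)
        traces, _ = process_traces(raw.fluorescence,
                                   default_track.frame_rate_hz)
        _, p = si_shuffle_test(traces[0].masked_dff, default_track, fam,
                               context=FAMILIAR, n_shuffles=200, seed=0)
        assert p < 0.05

    def test_zero_shuffles_rejected(self, default_track, openfield_pair):
        with pytest.raises(ValueError):
            si_shuffle_test(np.ones(default_track.n_frames), default_track,
                            openfield_pair[0], n_shuffles=0)

    def test_short_trace_rejected(self, openfield_pair):
        from ecdg.synthetic import simulate_behavior
        tiny = simulate_behavior(openfield_pair, n_runs_per_context=1,
                                 block_size=1, seed=0)
        with pytest.raises(ValueError, match="shorter"):
            si_shuffle_test(np.ones(tiny.n_frames), tiny,
                            openfield_pair[0], n_shuffles=10)


class TestSpeed:
    def test_speed_locked_units_classified_by_sign(self, default_track):
        sel_speed = default_track.speed_cm_s
        rng = np.random.default_rng(13)
        up = 0.1 * sel_speed + 0.2 * rng.standard_normal(sel_speed.size)
        down = -0.1 * sel_speed + 0.2 * rng.standard_normal(sel_speed.size)
        _, score_up, cls_up = speed_metrics(up, default_track,
                                            n_shuffles=200, seed=1)
        _, score_dn, cls_dn = speed_metrics(down, default_track,
                                            n_shuffles=200, seed=1)
        assert cls_up == "+" and score_up > 0
        assert cls_dn == "-" and score_dn < 0

    def test_constant_speed_undefined(self, default_track):
        track = default_track
        import copy

        flat = copy.copy(track)
        flat.speed_cm_s = np.full(track.n_frames, 20.0)
        info, score, cls = speed_metrics(np.ones(track.n_frames), flat,
                                         n_shuffles=10, seed=0)
        assert np.isnan(score) and cls == "NS"


class TestAds:
    @pytest.mark.parametrize("a,b,expected", [
        (0.3, 0.3, 0.0), (0.7, 0.0, 1.0), (0.3, 0.1, 0.5),
    ])
    def test_examples(self, a, b, expected):
        assert activity_difference_score(a, b) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        assert np.isnan(activity_difference_score(0.0, 0.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 100, allow_nan=False),
           st.floats(0, 100, allow_nan=False))
    def test_symmetric_and_bounded(self, a, b):
        if a + b == 0:
            return
        ads = activity_difference_score(a, b)
        assert 0.0 <= ads <= 1.0
        assert ads == activity_difference_score(b, a)


class TestRateAndLicks:
    def test_transient_rate_and_strict_active_threshold(self, short_track):
        t = short_track
        running = np.flatnonzero(t.running_mask())
        seconds = running.size / t.frame_rate_hz
        at_most_one_per_min = int(seconds // 60)  # rate <= 1/min
        for n, expect_active in [(at_most_one_per_min, False),
                                 (2 * at_most_one_per_min, True)]:
            onsets = running[np.linspace(0, running.size - 1, n, dtype=int)]
            iv = np.c_[onsets, onsets + 1]
            rate, active = transient_rate_and_active(iv, t)
            assert rate == pytest.approx(n / seconds)
            assert active is expect_active

    def test_reward_zone_spans_six_bins(self, openfield_pair,
                                        corridor_pair):
        assert reward_zone_bins(openfield_pair[0]).size == 6
        assert reward_zone_bins(corridor_pair[0]).size == 12  # two rewards

    def test_lick_ratio_uniform_and_zone_only(self, short_track,
                                              openfield_pair):
        fam = openfield_pair[0]
        import copy

        t = copy.copy(short_track)
        t.lick_flag = np.ones(t.n_frames, bool)
        assert lick_ratio(t, fam, FAMILIAR) == pytest.approx(1.0)
        zone = reward_zone_bins(fam)
        from ecdg.metrics import position_bins
        bins = position_bins(t.position_m, fam.bin_size_m, fam.n_bins)
        t2 = copy.copy(short_track)
        t2.lick_flag = np.isin(bins, zone)
        assert lick_ratio(t2, fam, FAMILIAR) == np.inf

    def test_simulated_licking_concentrates_at_rewards(self, default_track,
                                                       openfield_pair):
        ratio = lick_ratio(default_track, openfield_pair[0], FAMILIAR)
        assert ratio > 3.0
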