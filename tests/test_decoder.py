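import numpy as np
import pytest

from ecdg.decoder import (
    DecodedSeries, build_templates, chance_errors,
    cumulative_context_accuracy, decode_timebins, decoding_errors,
    default_split, efficiency_indices, split_runs, template_ratio,
    uniform_chance_spatial_error_cm,
)
from ecdg.environments import FAMILIAR, NOVEL
from ecdg.remapping import pearson
from ecdg.synthetic import simulate_units


def _series(true_ctx, true_bin, dec_ctx, dec_bin):
    n = len(true_ctx)
    return DecodedSeries(
        time_s=0.1 * np.arange(n), run_index=np.zeros(n, int),
        true_context=np.asarray(true_ctx), true_bin=np.asarray(true_bin),
        decoded_context=np.asarray(dec_ctx),
        decoded_bin=np.asarray(dec_bin),
        peak_r=np.ones(n), excluded=np.zeros(n, bool))


class TestSplit:
    def test_15_runs_split_8_template_7_test(self):
        tpl, tst = split_runs(np.arange(15))
        assert tpl.size == 8 and tst.size == 7
        assert set(tpl) | set(tst) == set(range(15))
        assert np.all(tpl[:-1] < tst[: tpl.size - 1])  # interleaved

    def test_two_runs_split_one_one(self):
        tpl, tst = split_runs(np.array([4, 9]))
        assert tpl.tolist() == [4] and tst.tolist() == [9]

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            split_runs(np.array([3]))


class TestTemplates:
    def test_constant_unit_spatial_rows_equal_mean_rate(self, default_track,
                                                        openfield_pair):
        fam = openfield_pair[0]
        X = np.vstack([np.full(default_track.n_frames, 2.0),
                       np.full(default_track.n_frames, 0.5)])
        template_runs, _ = default_split(default_track)
        spatial = build_templates(X, default_track, fam, template_runs,
                                  mode="spatial")
        rate = build_templates(X, default_track, fam, template_runs,
                               mode="mean_rate")
        assert spatial.matrix.shape == (160, 2)
        assert rate.matrix.shape == (2, 2)
        assert np.allclose(spatial.matrix, [2.0, 0.5])
        assert np.allclose(rate.matrix, [2.0, 0.5])

    def test_unknown_mode_rejected(self, default_track, openfield_pair):
        template_runs, _ = default_split(default_track)
        with pytest.raises(ValueError, match="mode"):
            build_templates(np.ones((2, default_track.n_frames)),
                            default_track, openfield_pair[0],
                            template_runs, mode="bayes")


class TestDecode:
    def _noiseless_setup(self, track, pair, n_units=12, seed=41):
        from ecdg.synthetic import tuning_curve_activity

        units = simulate_units({"place": 1.0}, n_units, pair, seed=seed)
        return tuning_curve_activity(units, track)

    def test_decoded_series_matches_bruteforce_correlation(
            self, default_track, openfield_pair):
        fam = openfield_pair[0]
        X = self._noiseless_setup(default_track, openfield_pair)
        template_runs, test_runs = default_split(default_track)
        templates = build_templates(X, default_track, fam, template_runs)
        series = decode_timebins(X, default_track, fam, templates,
                                 test_runs)
        from ecdg.decoder import _population_vectors
        V, *_ = _population_vectors(X, default_track, fam, test_runs, 0.1,
                                    5.0)
        T = templates.matrix
        for g in np.flatnonzero(~series.excluded)[:40]:
            rs = np.array([pearson(V[g], T[row])
                           for row in range(T.shape[0])])
            rs[np.isnan(rs)] = -np.inf
            best = int(np.argmax(rs))
            assert templates.row_context[best] == series.decoded_context[g]
            assert templates.row_bin[best] == series.decoded_bin[g]

    def test_noiseless_tuned_pool_decodes_context_and_position(
            self, default_track, openfield_pair):
        fam = openfield_pair[0]
        X = self._noiseless_setup(default_track, openfield_pair, n_units=25,
                                  seed=42)
        template_runs, test_runs = default_split(default_track)
        templates = build_templates(X, default_track, fam, template_runs)
        series = decode_timebins(X, default_track, fam, templates,
                                 test_runs)
        err = decoding_errors(series, fam.bin_size_m)
        assert err.context_error == 0.0
        assert err.spatial_error_cm <= 5.0

    def test_fewer_than_two_units_rejected(self, default_track,
                                           openfield_pair):
        fam = openfield_pair[0]
        template_runs, test_runs = default_split(default_track)
        X = np.ones((2, default_track.n_frames))
        templates = build_templates(X, default_track, fam, template_runs)
        with pytest.raises(ValueError):
            decode_timebins(X[:1], default_track, fam, templates,
                            test_runs)


class TestErrors:
    def test_perfect_decoding_gives_zero_errors(self):
        s = _series([0, 1, 0, 1], [3, 40, 7, 70], [0, 1, 0, 1],
                    [3, 40, 7, 70])
        err = decoding_errors(s)
        assert err.context_error == 0.0
        assert err.spatial_error_cm == 0.0

    def test_all_contexts_wrong(self):
        s = _series([0, 0, 1], [1, 2, 3], [1, 1, 0], [1, 2, 3])
        assert decoding_errors(s).context_error == 1.0

    def test_uniform_random_bins_match_closed_form(self):
        rng = np.random.default_rng(0)
        n = 200_000
        s = _series(np.zeros(n, int), rng.integers(0, 80, n),
                    np.zeros(n, int), rng.integers(0, 80, n))
        err = decoding_errors(s)
        assert err.spatial_error_cm == pytest.approx(133.3125, rel=0.01)

    def test_closed_form_value(self):
        # brute-force mean |i - j| * 5 cm over all 80 x 80 bin pairs
        assert uniform_chance_spatial_error_cm() == pytest.approx(133.3125)

    def test_chance_context_error_near_half_and_reproducible(self):
        rng = np.random.default_rng(1)
        n = 4000
        true_ctx = rng.integers(0, 2, n)
        s = _series(true_ctx, rng.integers(0, 80, n),
                    rng.integers(0, 2, n), rng.integers(0, 80, n))
        ce1, se1 = chance_errors(s, n_shuffles=15, seed=3)
        ce2, _ = chance_errors(s, n_shuffles=15, seed=3)
        assert ce1 == ce2
        assert ce1 == pytest.approx(0.5, abs=0.03)
        assert se1 == pytest.approx(133.3125, rel=0.05)


class TestCumulative:
    def test_perfect_ensemble_reaches_target_in_first_bin(self):
        s = _series([0] * 50 + [1] * 50, np.zeros(100, int),
                    [0] * 50 + [1] * 50, np.zeros(100, int))
        acc = cumulative_context_accuracy(s, np.array([0.1, 0.5]))
        assert np.all(acc == 1.0)

    def test_chance_ensemble_never_reaches_target(self):
        rng = np.random.default_rng(2)
        s = _series(np.zeros(600, int), np.zeros(600, int),
                    rng.integers(0, 2, 600), np.zeros(600, int))
        acc = cumulative_context_accuracy(s, np.array([0.1, 1.0, 5.0]))
        assert np.all(acc < 0.9)

    def test_majority_vote_improves_with_segment_length(self):
        rng = np.random.default_rng(3)
        dec = np.where(rng.random(2000) < 0.35, 1, 0)  # 65% correct bins
        s = _series(np.zeros(2000, int), np.zeros(2000, int), dec,
                    np.zeros(2000, int))
        acc = cumulative_context_accuracy(s, np.array([0.1, 2.0, 10.0]))
        assert acc[0] < acc[1] < acc[2]


class TestEfficiency:
    def test_printed_example(self):
        from ecdg.decoder import DecodingErrors

        err = DecodingErrors(context_error=0.1, spatial_error_cm=50.0)
        cde, sde = efficiency_indices(err, 0.5, 130.0, 0.02)
        assert cde == pytest.approx(np.log(0.4 / 0.02))  # ln 20 ~ 3.00
        assert sde == pytest.approx(np.log(80.0 / 0.02))

    def test_no_gain_gives_sentinel(self):
        from ecdg.decoder import DecodingErrors

        err = DecodingErrors(context_error=0.5, spatial_error_cm=133.0)
        cde, _ = efficiency_indices(err, 0.5, 133.0, 0.02)
        assert cde == float("-inf")

    def test_halving_rate_adds_ln2(self):
        from ecdg.decoder import DecodingErrors

        err = DecodingErrors(context_error=0.1, spatial_error_cm=50.0)
        cde1, _ = efficiency_indices(err, 0.5, 130.0, 0.02)
        cde2, _ = efficiency_indices(err, 0.5, 130.0, 0.01)
        assert cde2 - cde1 == pytest.approx(np.log(2))

    def test_template_ratio(self):
        assert template_ratio(0.2, 0.2) == 1.0
        assert template_ratio(0.1, 0.4) == pytest.approx(0.25)
        assert template_ratio(0.1, 0.0) == float("inf")
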