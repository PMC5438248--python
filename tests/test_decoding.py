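import numpy as np
import pytest

from paincode import (DecodingResult, GeneratorConfig, aggregate_sessions,
                      build_cumulative_features, evaluate_decoder,
                      generate_mixed_session, permutation_chance)
from paincode.decoding import DecodingError

from conftest import make_session


def _null_session(seed, n_units=3, n_each=15):
    cfg = GeneratorConfig(n_units=n_units, evoked_amplitude_hz={}, rng_seed=0)
    return generate_mixed_session(cfg, ("NS", "HS"), seed=seed, n_each=n_each)


def _separable_session(seed, n_units=5, n_each=10):
    cfg = GeneratorConfig(n_units=n_units, evoked_amplitude_hz={"HS": 12.0},
                          fraction_responsive=1.0, rng_seed=0)
    return generate_mixed_session(cfg, ("NS", "HS"), seed=seed, n_each=n_each)


def test_cumulative_feature_dimensions_grow_linearly(small_mixed_session):
    feats = build_cumulative_features(small_mixed_session, 0.1, 5.0)
    assert feats.n_bins == 50
    C = feats.n_units
    assert feats.features_at(1).shape[1] == C
    assert feats.features_at(50).shape[1] == 50 * C


def test_single_spike_counts_once_in_every_cumulative_window():
    sess = make_session([("u0", 0, 0.05)],
                        [(0, "NS", np.nan, 50.0), (1, "HS", np.nan, 250.0)])
    feats = build_cumulative_features(sess, 0.1, 5.0)
    trial0 = list(feats.labels).index(0)
    for b in (1, 10, 50):
        assert feats.features_at(b)[trial0].sum() == 1


def test_cumulative_counts_match_manual_binning():
    sess = make_session(
        [("u0", 0, 0.05), ("u0", 0, 0.15), ("u0", 0, 0.25), ("u0", 1, 0.11)],
        [(0, "NS", np.nan, 50.0), (1, "HS", np.nan, 250.0)])
    feats = build_cumulative_features(sess, 0.1, 0.3)
    # trial 0: one spike in each of bins 1..3; trial 1: one spike in bin 2
    i0 = list(feats.labels).index(0)
    i1 = list(feats.labels).index(1)
    assert feats.features_at(3)[i0].tolist() == [1, 1, 1]
    assert feats.features_at(3)[i1].tolist() == [0, 1, 0]
    assert np.all(np.diff(feats.counts.cumsum(axis=1), axis=1) >= 0)


def test_three_stimulus_classes_rejected():
    sess = make_session([("u0", 0, 0.1)],
                        [(0, "NS", np.nan, 50.0), (1, "LS", np.nan, 150.0),
                         (2, "HS", np.nan, 250.0)])
    with pytest.raises(DecodingError, match="two stimulus classes"):
        build_cumulative_features(sess)


def test_uninformative_features_decode_at_chance():
    feats = build_cumulative_features(_null_session(3), 0.1, 1.0)
    res = evaluate_decoder(feats, folds=5, mc_repeats=4, seed=1)
    assert 0.35 < res.accuracy_mean.mean() < 0.65
    assert np.all(res.accuracy_mean >= 0) and np.all(res.accuracy_mean <= 1)
    assert np.all(res.accuracy_sem >= 0)


def test_separable_classes_reach_high_accuracy_by_late_bins():
    feats = build_cumulative_features(_separable_session(5), 0.1, 2.0)
    res = evaluate_decoder(feats, folds=5, mc_repeats=3, seed=2)
    assert res.accuracy_mean[-1] >= 0.9
    assert res.max_accuracy >= 0.9


def test_decoder_requires_enough_trials_per_class():
    feats = build_cumulative_features(_separable_session(5, n_each=4), 0.1, 1.0)
    with pytest.raises(DecodingError, match="5-fold"):
        evaluate_decoder(feats, folds=5, mc_repeats=1)


def test_decoder_invariant_to_unit_order():
    sess = _separable_session(7, n_each=8)
    feats = build_cumulative_features(sess, 0.1, 1.0)
    sess2 = sess.subset_units(list(reversed(sess.units)))
    sess2.units = list(reversed(sess.units))
    feats2 = build_cumulative_features(sess2, 0.1, 1.0)
    r1 = evaluate_decoder(feats, folds=4, mc_repeats=2, seed=9)
    r2 = evaluate_decoder(feats2, folds=4, mc_repeats=2, seed=9)
    assert np.allclose(r1.accuracy_mean, r2.accuracy_mean)


def test_permutation_chance_near_half_for_balanced_labels():
    feats = build_cumulative_features(_separable_session(11, n_each=10), 0.1, 1.0)
    curve = permutation_chance(feats, n_permutations=15, folds=5, seed=3)
    assert 0.35 < curve.mean() < 0.65


def test_permutation_count_must_be_positive():
    feats = build_cumulative_features(_separable_session(11, n_each=10), 0.1, 1.0)
    with pytest.raises(DecodingError):
        permutation_chance(feats, n_permutations=0)


def _result(session_id, n_units, max_acc):
    curve = np.full(5, max_acc)
    return DecodingResult(accuracy_mean=curve, accuracy_sem=np.zeros(5),
                          max_accuracy=max_acc, classes=("LS", "HS"),
                          n_units=n_units, n_trials_per_class=(10, 10),
                          bin_size_s=0.1, session_id=session_id)


class TestAggregate:
    def test_small_sessions_excluded_by_unit_filter(self):
        out = aggregate_sessions([_result("a", 7, 0.8), _result("b", 4, 0.99)],
                                 min_units=5)
        assert out["session_ids"] == ["a"]
        assert out["excluded_sessions"] == ["b"]

    def test_identical_sessions_have_zero_sem(self):
        out = aggregate_sessions([_result("a", 7, 0.8), _result("b", 7, 0.8)])
        assert out["max_accuracy_sem"] == 0.0

    def test_mean_matches_hand_average(self):
        out = aggregate_sessions([_result("a", 6, 0.7), _result("b", 6, 0.9),
                                  _result("c", 6, 0.8)])
        assert out["max_accuracy_mean"] == pytest.approx((0.7 + 0.9 + 0.8) / 3)

    def test_error_when_every_session_filtered(self):
        with pytest.raises(DecodingError, match="min_units"):
            aggregate_sessions([_result("a", 3, 0.8)], min_units=5)
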