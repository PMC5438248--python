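import numpy as np
import pandas as pd
import pytest

from paincode import (CountTensor, GeneratorConfig, bin_counts,
                      generate_session, zscore_psth)
from paincode.psth import PSTHError

from conftest import make_session


def test_onset_spike_falls_in_first_poststimulus_bin():
    # spikes at -0.1, 0.0, 0.05 with 200 ms bins: the onset spike belongs to
    # the first post-stimulus bin because bins are half-open [t, t+d)
    sess = make_session(
        [("u0", 0, -0.1), ("u0", 0, 0.0), ("u0", 0, 0.05)],
        [(0, "HS", 0.9, 250.0)])
    ct = bin_counts(sess, bin_size_s=0.2, window_s=5.0)
    assert ct.counts.shape == (1, 1, 50)
    assert ct.counts[0, 0, 24] == 1      # last baseline bin
    assert ct.counts[0, 0, 25] == 2      # first post-stimulus bin
    assert ct.counts.sum() == 3


def test_empty_unit_yields_all_zero_counts():
    sess = make_session([("u0", 0, 1.0)], [(0, "HS", np.nan, 250.0),
                                           (1, "HS", np.nan, 250.0)])
    sess.units = ["u0", "u_silent"]
    ct = bin_counts(sess, bin_size_s=0.2)
    assert ct.counts[1].sum() == 0


def test_five_second_window_gives_25_baseline_and_25_post_bins():
    sess = make_session([("u0", 0, 0.0)], [(0, "LS", np.nan, 150.0)])
    ct = bin_counts(sess, bin_size_s=0.2, window_s=5.0)
    assert ct.n_bins == 50
    assert ct.n_baseline_bins == 25


def test_bin_size_must_divide_window():
    sess = make_session([("u0", 0, 0.0)], [(0, "LS", np.nan, 150.0)])
    with pytest.raises(PSTHError, match="does not divide"):
        bin_counts(sess, bin_size_s=0.3, window_s=5.0)


def test_poisson_rate_recovered_by_trial_averaging():
    # 5 Hz stationary Poisson, many trials: mean count per 200 ms bin -> 1.0
    cfg = GeneratorConfig(n_units=1, baseline_log_mean=np.log(5.0),
                          baseline_log_sd=0.0, evoked_amplitude_hz={},
                          gain_sd=0.0, rng_seed=0)
    sess = generate_session(cfg, ["NS"] * 600, seed=1)
    ct = bin_counts(sess, bin_size_s=0.2)
    mean_count = ct.counts.mean()
    assert mean_count == pytest.approx(1.0, rel=0.05)


def _tensor_from_rates(rate_rows, bin_size_s=1.0):
    """CountTensor with identical trials whose bin rates are given exactly."""
    counts = np.tile(np.asarray(rate_rows) * bin_size_s, (2, 1))[None].astype(int)
    counts = counts.reshape(1, 2, -1)
    return CountTensor(counts=counts, bin_size_s=bin_size_s,
                       window_s=bin_size_s * counts.shape[2] / 2,
                       units=["u0"], trial_ids=np.array([0, 1]))


def test_zscore_matches_hand_arithmetic():
    # baseline bins with mean 4 Hz and SD 1 Hz; a post bin at 9 Hz has z = 5
    baseline = [3] * 12 + [5] * 12 + [4]          # mean 4, sample SD exactly 1
    post = [4] * 24 + [9]
    ct = _tensor_from_rates(baseline + post)
    m = zscore_psth(ct)
    assert m.fr_b_mean[0] == pytest.approx(4.0)
    assert m.fr_b_sd[0] == pytest.approx(1.0)
    assert m.z[0, -1] == pytest.approx(5.0)
    assert m.z[0, 25] == pytest.approx(0.0)       # post bin at baseline mean


def test_baseline_z_bins_have_mean_zero_sd_one(rng):
    counts = rng.poisson(1.5, size=(6, 40, 50))
    ct = CountTensor(counts=counts, bin_size_s=0.2, window_s=5.0,
                     units=[f"u{i}" for i in range(6)], trial_ids=np.arange(40))
    m = zscore_psth(ct)
    base = m.z[:, :25]
    assert np.allclose(base.mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose(base.std(axis=1, ddof=1), 1.0, atol=1e-12)


def test_zscore_invariant_to_unit_and_trial_order(rng):
    counts = rng.poisson(2.0, size=(4, 20, 50))
    ct = CountTensor(counts=counts, bin_size_s=0.2, window_s=5.0,
                     units=["a", "b", "c", "d"], trial_ids=np.arange(20))
    m = zscore_psth(ct)
    perm_u = [3, 0, 2, 1]
    perm_t = rng.permutation(20)
    ct2 = CountTensor(counts=counts[perm_u][:, perm_t], bin_size_s=0.2,
                      window_s=5.0, units=[ct.units[i] for i in perm_u],
                      trial_ids=np.arange(20))
    m2 = zscore_psth(ct2)
    assert np.allclose(m2.z, m.z[perm_u])


def test_degenerate_baseline_flagged_not_infinite():
    counts = np.zeros((1, 3, 50), dtype=int)
    counts[0, :, 30] = 4                          # silent baseline, active post bin
    ct = CountTensor(counts=counts, bin_size_s=0.2, window_s=5.0,
                     units=["u0"], trial_ids=np.arange(3))
    m = zscore_psth(ct)
    assert m.degenerate[0]
    assert np.all(np.isnan(m.z[0]))


def test_stationary_unit_post_z_centered_at_zero(rng):
    counts = rng.poisson(2.0, size=(40, 30, 50))
    ct = CountTensor(counts=counts, bin_size_s=0.2, window_s=5.0,
                     units=[f"u{i}" for i in range(40)], trial_ids=np.arange(30))
    m = zscore_psth(ct)
    assert abs(np.nanmean(m.post_z())) < 0.1
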