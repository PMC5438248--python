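import numpy as np
import pytest

from paincode import (CountTensor, GeneratorConfig, PSTHMatrix,
                      classify_responsive, compute_z_sem, generate_session,
                      identify_intensity_coding, zscore_psth)
from paincode.config import spawn_seeds


def _psth_from_post_z(z_post, z_sem_value=0.0):
    """Minimal PSTHMatrix with given post-stimulus z and flat baseline."""
    nb = len(z_post)
    z = np.concatenate([np.zeros(nb), np.asarray(z_post, float)])[None]
    m = PSTHMatrix(units=["u0"], z=z, fr=z + 4.0, fr_sem=np.full_like(z, z_sem_value),
                   fr_b_mean=np.array([4.0]), fr_b_sd=np.array([1.0]),
                   degenerate=np.array([False]), bin_size_s=0.2, window_s=nb * 0.2,
                   n_trials=10)
    return m


def test_z_sem_zero_when_trials_identical():
    counts = np.tile(np.arange(50)[None, None] % 3, (1, 8, 1))
    ct = CountTensor(counts=counts, bin_size_s=0.2, window_s=5.0,
                     units=["u0"], trial_ids=np.arange(8))
    m = zscore_psth(ct)
    z_sem = compute_z_sem(m)
    assert np.allclose(z_sem[0], 0.0)


def test_z_sem_matches_standard_error_arithmetic():
    # per-trial rates {8, 10, 12} Hz in one bin with baseline SD 1 Hz:
    # Z_SEM = SE({8,10,12}) / 1 = (2/sqrt(3))
    nb = 13
    base = np.array([3] * 6 + [5] * 6 + [4])      # mean 4, sample SD exactly 1
    counts = np.tile(np.concatenate([base, np.full(nb, 4)]), (3, 1))
    counts = counts[None].astype(int)              # (1, 3, 26), bin 1 s
    counts[0, :, nb] = [8, 10, 12]
    ct = CountTensor(counts=counts, bin_size_s=1.0, window_s=float(nb),
                     units=["u0"], trial_ids=np.arange(3))
    m = zscore_psth(ct)
    assert m.fr_b_sd[0] == pytest.approx(1.0)
    z_sem = compute_z_sem(m)
    assert z_sem[0, nb] == pytest.approx(2.0 / np.sqrt(3.0))


def test_rate_standard_error_shrinks_with_sqrt_of_trial_count():
    # same per-trial variance, 4x the trials: the across-trial SE of the bin
    # rate halves.  (Z_SEM itself is roughly scale-stable: its denominator,
    # the baseline SD of the trial-averaged rate, shrinks by the same factor.)
    def stats_for(n_trials, seed):
        counts = np.random.default_rng(seed).poisson(2.0, size=(1, n_trials, 50))
        m = zscore_psth(CountTensor(counts=counts, bin_size_s=0.2, window_s=5.0,
                                    units=["u0"], trial_ids=np.arange(n_trials)))
        return m.fr_sem.mean(), np.nanmean(compute_z_sem(m))

    small = np.mean([stats_for(200, s) for s in range(5)], axis=0)
    large = np.mean([stats_for(800, s + 10) for s in range(5)], axis=0)
    assert small[0] / large[0] == pytest.approx(2.0, rel=0.1)
    assert small[1] / large[1] == pytest.approx(1.0, rel=0.15)


def test_all_zero_z_is_not_responsive():
    res = classify_responsive(_psth_from_post_z(np.zeros(25)))
    assert not res[0].is_responsive


def test_two_strong_bins_pass_both_criteria():
    z_post = np.zeros(25)
    z_post[[3, 7]] = 3.0
    m = _psth_from_post_z(z_post, z_sem_value=0.5)
    res = classify_responsive(m)[0]
    assert res.is_responsive
    assert set(res.bins_criterion_1) == {3, 7}
    assert set(res.bins_criterion_2) == {3, 7}     # 3.0 - 0.5 = 2.5 > 1.645


def test_single_strong_bin_is_insufficient():
    z_post = np.zeros(25)
    z_post[5] = 5.0
    assert not classify_responsive(_psth_from_post_z(z_post))[0].is_responsive


def test_degenerate_baseline_unit_is_indeterminate():
    m = _psth_from_post_z(np.full(25, 9.0))
    m.degenerate = np.array([True])
    res = classify_responsive(m)[0]
    assert res.indeterminate and not res.is_responsive


def test_positive_shift_never_silences_excitatory_responses(rng):
    # for units whose criterion evidence is excitatory (positive z), adding a
    # uniform positive increment to the post-stimulus z never flips a
    # responsive unit to non-responsive
    for _ in range(200):
        z_post = rng.normal(1.5, 1.5, size=25).clip(min=0)
        z_sem = abs(rng.normal(0.5, 0.3))
        m = _psth_from_post_z(z_post, z_sem_value=z_sem)
        if not classify_responsive(m)[0].is_responsive:
            continue
        shifted = _psth_from_post_z(z_post + rng.uniform(0, 3), z_sem_value=z_sem)
        assert classify_responsive(shifted)[0].is_responsive


def test_decision_uses_only_post_stimulus_bins():
    z_post = np.zeros(25)
    z_post[[0, 1]] = 4.0
    m = _psth_from_post_z(z_post, z_sem_value=0.1)
    m.z[0, :25] = 9.0                              # wild baseline bins: irrelevant
    assert classify_responsive(m)[0].is_responsive


class TestIntensityCoding:
    def _session(self, amps, seed, n_units=6, n_trials=20):
        cfg = GeneratorConfig(n_units=n_units, evoked_amplitude_hz=amps,
                              fraction_responsive=1.0, rng_seed=0)
        labels = ["LS", "HS"] * (n_trials // 2)
        return generate_session(cfg, labels * 2, seed=seed, session_id="ic")

    def test_clear_amplitude_difference_is_detected(self):
        sess = self._session({"LS": 4.0, "HS": 12.0}, seed=5)
        res = identify_intensity_coding(sess.units, sess, sess)
        assert len(res) > 0
        assert np.mean([r.hs_gt_ls for r in res]) >= 0.8

    def test_null_flag_rate_calibrated_with_index_pairing(self):
        # identical LS and HS generators, exchangeable pairing: the flagged
        # fraction stays near the nominal one-sided test level
        flags = []
        for s in spawn_seeds(7, 30):
            sess = self._session({"LS": 5.0, "HS": 5.0}, seed=s)
            res = identify_intensity_coding(sess.units, sess, sess,
                                            pairing="index")
            flags.extend(r.hs_gt_ls for r in res)
        assert np.mean(flags) < 0.12

    def test_only_requested_units_are_tested(self):
        sess = self._session({"LS": 4.0, "HS": 12.0}, seed=5)
        res = identify_intensity_coding(sess.units[:2], sess, sess)
        assert {r.unit_id for r in res} <= set(sess.units[:2])
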