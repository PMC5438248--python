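import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paincode import (FILAMENTS_G, GeneratorConfig, VonFreySequence,
                      cpa_score, cpa_score_for_stimulus, filter_cpa_baseline,
                      generate_cpa_cohort, generate_session,
                      simulate_updown_sequence, updown_50pct_threshold,
                      withdrawal_summary, withdrawal_velocity)
from paincode.behavior import BehaviorError, _log_units, _ml_threshold_log
from paincode.io import ChamberOccupancy, CPARecord


def _record(base_a, test_a, phase=600.0, stim=("LS", "NS")):
    return CPARecord(animal_id="a0", group="g", chambers={
        "A": ChamberOccupancy(base_a, test_a, stim[0]),
        "B": ChamberOccupancy(phase - base_a, phase - test_a, stim[1])})


class TestCPA:
    def test_unbiased_animal_kept(self):
        kept, excluded = filter_cpa_baseline([_record(300, 200)])
        assert len(kept) == 1 and not excluded

    def test_extreme_baseline_bias_excluded(self):
        kept, excluded = filter_cpa_baseline([_record(501, 300)])
        assert not kept
        assert "501" in excluded[0][1]

    def test_filter_partitions_input(self):
        records = [_record(b, 300) for b in (50, 150, 300, 450, 550)]
        kept, excluded = filter_cpa_baseline(records)
        assert len(kept) + len(excluded) == len(records)
        assert set(id(r) for r in kept).isdisjoint(id(r) for r, _ in excluded)
        kept2, excluded2 = filter_cpa_baseline(kept)
        assert kept2 == kept and not excluded2          # idempotent

    def test_score_is_baseline_minus_test(self):
        assert cpa_score(_record(300, 200), "A") == pytest.approx(100.0)
        assert cpa_score(_record(250, 250), "A") == pytest.approx(0.0)
        assert cpa_score_for_stimulus(_record(300, 200), "LS") == pytest.approx(100.0)

    def test_chamber_scores_are_antisymmetric(self):
        rec = _record(320, 180)
        assert cpa_score(rec, "A") + cpa_score(rec, "B") == pytest.approx(0.0)

    def test_unknown_chamber_rejected(self):
        with pytest.raises(BehaviorError):
            cpa_score(_record(300, 200), "C")

    def test_occupancy_conserved_in_generated_cohorts(self):
        cohort = generate_cpa_cohort(GeneratorConfig(), 40, 120.0, seed=8)
        for rec in cohort:
            base = sum(o.baseline_s for o in rec.chambers.values())
            test = sum(o.test_s for o in rec.chambers.values())
            assert base == pytest.approx(600.0)
            assert test == pytest.approx(600.0)

    def test_zero_effect_gives_zero_mean_score(self):
        cohort = generate_cpa_cohort(GeneratorConfig(), 400, 0.0, seed=9)
        kept, _ = filter_cpa_baseline(cohort)
        scores = [cpa_score_for_stimulus(r, "LS") for r in kept]
        assert abs(np.mean(scores)) < 3 * np.std(scores) / np.sqrt(len(scores)) + 1.0

    def test_noiseless_effect_recovered_exactly(self):
        cfg = GeneratorConfig(cpa_test_noise_sd_s=0.0)
        cohort = generate_cpa_cohort(cfg, 10, 100.0, seed=10)
        kept, _ = filter_cpa_baseline(cohort)
        for rec in kept:
            assert cpa_score_for_stimulus(rec, "LS") == pytest.approx(100.0)

    def test_default_bias_excludes_about_one_fifth(self):
        cohort = generate_cpa_cohort(GeneratorConfig(), 3000, 0.0, seed=11)
        _, excluded = filter_cpa_baseline(cohort)
        assert 0.15 < len(excluded) / len(cohort) < 0.25

    def test_effect_exceeding_phase_duration_rejected(self):
        with pytest.raises(Exception, match="phase"):
            generate_cpa_cohort(GeneratorConfig(), 5, 700.0, seed=1)


class TestUpDown:
    def test_all_responses_clamp_to_smallest_filament(self):
        seq = VonFreySequence("XXXXXX")
        assert updown_50pct_threshold(seq) == pytest.approx(FILAMENTS_G[0])

    def test_no_responses_clamp_to_largest_filament(self):
        seq = VonFreySequence("OOOOOO")
        assert updown_50pct_threshold(seq) == pytest.approx(FILAMENTS_G[-1])

    def test_short_monotone_sequence_rejected(self):
        with pytest.raises(BehaviorError, match="monotone"):
            updown_50pct_threshold(VonFreySequence("XX"))

    def test_estimate_matches_grid_search_oracle(self):
        for pattern in ("OXOXOX", "XOXOXO", "OOXOXX", "XXOXOO"):
            seq = VonFreySequence(pattern)
            fil = np.asarray(seq.filaments_g)
            x = _log_units(fil)[seq.applied_indices()]
            r = np.array([1.0 if c == "X" else 0.0 for c in pattern])
            delta = float(np.mean(np.diff(_log_units(fil))))
            grid = np.arange(x.min() - 6 * delta, x.max() + 6 * delta, 1e-4)
            nll = [-np.sum(r * stats.norm.logcdf((x - m) / delta)
                           + (1 - r) * stats.norm.logsf((x - m) / delta))
                   for m in grid]
            expected = np.clip(10 ** grid[int(np.argmin(nll))] / 1e4,
                               fil[0], fil[-1])
            assert updown_50pct_threshold(seq) == pytest.approx(expected, abs=1e-3)

    def test_extra_response_never_raises_ml_threshold(self, rng):
        # at fixed applied forces, converting a no-response to a response can
        # only pull the maximum-likelihood threshold down
        fil = np.asarray(FILAMENTS_G)
        delta = float(np.mean(np.diff(_log_units(fil))))
        for _ in range(50):
            x = _log_units(rng.choice(fil, size=6))
            r = rng.integers(0, 2, size=6).astype(float)
            base = _ml_threshold_log(x, r, delta)
            for i in np.flatnonzero(r == 0):
                flipped = r.copy()
                flipped[i] = 1.0
                assert _ml_threshold_log(x, flipped, delta) <= base + 1e-6

    def test_sequence_level_flip_monotonicity(self):
        # exhaustive over 6-step staircases: flipping any O to X (with the
        # implied restaircasing) never increases the estimated threshold
        import itertools
        for bits in itertools.product("XO", repeat=6):
            pattern = "".join(bits)
            seq = VonFreySequence(pattern)
            try:
                base = updown_50pct_threshold(seq)
            except BehaviorError:
                continue
            for i, c in enumerate(pattern):
                if c != "O":
                    continue
                flipped = VonFreySequence(pattern[:i] + "X" + pattern[i + 1:])
                try:
                    new = updown_50pct_threshold(flipped)
                except BehaviorError:
                    continue
                assert new <= base + 1e-6

    def test_simulated_staircases_track_true_threshold(self):
        low = [updown_50pct_threshold(simulate_updown_sequence(1.0, seed=s))
               for s in range(5)]
        high = [updown_50pct_threshold(simulate_updown_sequence(8.0, seed=s))
                for s in range(5)]
        assert np.mean(low) < np.mean(high)
        assert all(FILAMENTS_G[0] <= t <= FILAMENTS_G[-1] for t in low + high)

    def test_staircase_replay_steps_down_after_response(self):
        seq = VonFreySequence("OXOXOX")
        idx = seq.applied_indices()
        for i, r in enumerate(seq.responses[:-1]):
            step = idx[i + 1] - idx[i]
            assert step == (1 if r == "O" else -1)


class TestWithdrawal:
    def test_equal_latencies_have_zero_sem(self):
        trials = pd.DataFrame({"stimulus": ["HS"] * 4,
                               "withdrawal_latency_s": [1.5] * 4})
        out = withdrawal_summary(trials)
        assert out.loc[0, "latency_sem_s"] == 0.0

    def test_generator_defaults_order_latencies_and_ns_rate(self):
        cfg = GeneratorConfig(n_units=1, rng_seed=0)
        labels = ["HS"] * 150 + ["LS"] * 150 + ["NS"] * 400
        sess = generate_session(cfg, labels, seed=21)
        out = withdrawal_summary(sess.trials).set_index("stimulus")
        assert out.loc["HS", "latency_mean_s"] < out.loc["LS", "latency_mean_s"]
        assert out.loc["NS", "withdrawal_fraction"] < 0.05
        assert out.loc["HS", "withdrawal_fraction"] == 1.0
        assert out.loc["LS", "withdrawal_fraction"] == 1.0

    def test_velocity_is_height_over_time(self):
        v = withdrawal_velocity([0.10, 0.08], [0.05, 0.04])
        assert np.allclose(v, [2.0, 2.0])
        with pytest.raises(BehaviorError):
            withdrawal_velocity([0.1], [0.0])
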