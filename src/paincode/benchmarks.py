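"""Calibration experiments run on synthetic data.

Each function regenerates its inputs from a seed and runs the corresponding
analysis end to end, so the recovered quantities measure the pipeline rather
than stored numbers: tuning-slope recovery across replicated cohorts, the
decoding ceiling on strongly separable sessions, and the permutation chance
level on balanced sessions.
"""

from __future__ import annotations

import numpy as np

from .config import spawn_seeds
from .decoding import build_cumulative_features, evaluate_decoder, permutation_chance
from .synth import GeneratorConfig, generate_mixed_session, generate_tuning_cohort
from .tuning import fit_tuning_from_pairs

# study conditions of the two tuning regimes: printed slope, R^2 and
# population size of the steep (pre-injury) and flattened (chronic-pain) fits
PRE_CFA_TUNING = {"slope": 1.31, "slope_se": 0.09, "r_squared": 0.5937, "n": 50}
POST_CFA_TUNING = {"slope": 1.07, "slope_se": 0.07, "r_squared": 0.6904, "n": 53}


def tuning_slope_recovery(generating_slope: float, r_squared: float, n_neurons: int,
                          n_replicates: int = 200, seed: int = 0) -> dict:
    """Mean robust-regression slope over replicated synthetic cohorts.

    Each replicate draws ``n_neurons`` (LS, HS) peak pairs at the generating
    slope with noise calibrated to the target R^2, fits the bisquare robust
    regression, and the fitted slopes are averaged.
    """
    slopes = np.empty(n_replicates)
    for i, s in enumerate(spawn_seeds(seed, n_replicates)):
        pairs = generate_tuning_cohort(n_neurons, generating_slope, seed=s,
                                       r_squared=r_squared)
        slopes[i] = fit_tuning_from_pairs(pairs).slope
    return {
        "mean_slope": float(slopes.mean()),
        "sem_slope": float(slopes.std(ddof=1) / np.sqrt(n_replicates)),
        "n_neurons": n_neurons,
        "n_replicates": n_replicates,
    }


def _separable_config(seed: int) -> GeneratorConfig:
    # one class evokes a large transient (~5x the 2 Hz baseline at peak, well
    # over 4 baseline SDs of the binned rate), the other evokes nothing
    return GeneratorConfig(
        n_units=7, n_trials_mixed=30, baseline_log_mean=np.log(2.0),
        baseline_log_sd=0.3, evoked_amplitude_hz={"NS": 0.0, "HS": 10.0},
        fraction_responsive=1.0, rng_seed=seed)


def decoding_ceiling(seed: int = 0, n_sessions: int = 9, trials_per_class: int = 30,
                     folds: int = 5, mc_repeats: int = 20,
                     bin_size_s: float = 0.1, horizon_s: float = 5.0) -> dict:
    """Mean per-session maximum cumulative decoding accuracy (strong signal).

    Nine sessions of 7 units discriminating a strongly driven class from a
    silent class; reported in percent.
    """
    maxima = []
    for s in spawn_seeds(seed, n_sessions):
        cfg = _separable_config(s)
        sess = generate_mixed_session(cfg, ("NS", "HS"), seed=s,
                                      n_each=trials_per_class,
                                      session_id=f"sep{s % 1000}")
        feats = build_cumulative_features(sess, bin_size_s=bin_size_s,
                                          horizon_s=horizon_s)
        res = evaluate_decoder(feats, folds=folds, mc_repeats=mc_repeats, seed=s)
        maxima.append(res.max_accuracy)
    maxima = np.asarray(maxima)
    return {
        "mean_max_accuracy_pct": float(100 * maxima.mean()),
        "sem_max_accuracy_pct": float(100 * maxima.std(ddof=1) / np.sqrt(len(maxima))),
        "per_session_pct": (100 * maxima).tolist(),
        "n_sessions": n_sessions,
    }


def balanced_permutation_chance(seed: int = 0, trials_per_class: int = 28,
                                n_permutations: int = 100, folds: int = 5,
                                bin_size_s: float = 0.1, horizon_s: float = 5.0) -> dict:
    """Mean shuffled-label decoding accuracy on a balanced informative session.

    Labels of a balanced (equal class counts) session with a real evoked
    signal are permuted ``n_permutations`` times and the full cross-validated
    decoding is re-run each time; the average accuracy over permutations and
    evaluation bins estimates the empirical chance level, in percent.
    """
    s0, s1 = spawn_seeds(seed, 2)
    cfg = _separable_config(s0)
    sess = generate_mixed_session(cfg, ("NS", "HS"), seed=s0,
                                  n_each=trials_per_class, session_id="chance")
    feats = build_cumulative_features(sess, bin_size_s=bin_size_s,
                                      horizon_s=horizon_s)
    curve = permutation_chance(feats, n_permutations=n_permutations,
                               folds=folds, seed=s1)
    return {
        "chance_mean_pct": float(100 * curve.mean()),
        "chance_curve_pct": (100 * curve).tolist(),
        "n_permutations": n_permutations,
        "trials_per_class": trials_per_class,
    }
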