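"""Synthetic spike sessions and behavioral cohorts.

The generator emulates the statistical structure the analysis assumes:
sessions of a handful of simultaneously recorded cortical units, ~35 trials
per stimulus class (or ~30+30 randomly interleaved trials of two classes at
~1 min inter-trial intervals), baseline Poisson firing with an
intensity-scaled transient evoked response, and behavioral cohorts for the
place-aversion and staircase assays.

Spike trains are inhomogeneous Poisson: rate(t) = b for t < 0 and
b + g * A_s * k(t) for t >= 0, where b is the unit's baseline rate (drawn
log-normally across units), A_s the evoked peak amplitude of stimulus class
s, g a per-trial multiplicative gain, and k(t) a normalized transient kernel
(linear rise over 0.5 s, exponential decay, peak 1).  Non-responsive units
have A = 0 for every class.

Two tuning regimes set the class amplitudes: ``pre_cfa`` has a steep
HS-vs-LS amplitude ratio and ``post_cfa`` compresses the LS amplitude toward
the HS amplitude (response saturation), flattening the tuning; the default
ratios (10/7.6 and 10/9.3) were chosen to land generated peak-response
tuning slopes near 1.3 and 1.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import LASER_MW, CPARecord, ChamberOccupancy, SpikeSession

PRE_CFA_AMPLITUDES = {"NS": 0.0, "LS": 7.6, "HS": 10.0}
POST_CFA_AMPLITUDES = {"NS": 0.0, "LS": 9.3, "HS": 10.0}


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic recordings and behavior cohorts.

    Rates are in Hz, times in seconds.  ``evoked_amplitude_hz`` overrides the
    regime amplitudes when given.
    """

    n_units: int = 7
    n_trials: int = 35                      # single-class session
    n_trials_mixed: int = 30                # per class in a two-class session
    window_s: float = 5.0
    baseline_log_mean: float = math.log(2.0)   # log-normal across units, median 2 Hz
    baseline_log_sd: float = 0.4
    tuning_regime: str = "pre_cfa"
    evoked_amplitude_hz: dict | None = None
    kernel_rise_s: float = 0.5
    kernel_decay_s: float = 1.5
    gain_sd: float = 0.15                   # per-trial multiplicative gain noise
    fraction_responsive: float = 0.8
    iti_mean_s: float = 60.0
    iti_sd_s: float = 10.0
    # withdrawal latency: shifted gamma per class, means HS < LS, NS rarely
    withdrawal_shape: float = 4.0
    withdrawal_params: dict = field(default_factory=lambda: {
        "LS": {"shift_s": 0.8, "mean_s": 3.0},
        "HS": {"shift_s": 0.4, "mean_s": 1.5},
    })
    ns_withdrawal_prob: float = 0.03
    # place-aversion cohorts
    cpa_phase_s: float = 600.0
    cpa_baseline_sd_s: float = 156.0        # ~20% of N(300, sd) falls outside [100, 500]
    cpa_test_noise_sd_s: float = 60.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_trials < 1 or self.n_trials_mixed < 1:
            raise GeneratorError("counts must be positive")
        if self.tuning_regime not in ("pre_cfa", "post_cfa"):
            raise GeneratorError("tuning_regime must be 'pre_cfa' or 'post_cfa'")
        amps = self.amplitudes()
        if any(a < 0 for a in amps.values()):
            raise GeneratorError("evoked amplitudes must be nonnegative")
        if self.evoked_amplitude_hz is None and self.tuning_regime == "pre_cfa" \
                and not (amps["NS"] <= amps["LS"] <= amps["HS"]):
            raise GeneratorError("pre_cfa amplitudes must be ordered NS <= LS <= HS")
        if self.gain_sd < 0 or self.fraction_responsive < 0 or self.fraction_responsive > 1:
            raise GeneratorError("gain_sd >= 0 and fraction_responsive in [0, 1] required")

    def amplitudes(self) -> dict:
        if self.evoked_amplitude_hz is not None:
            amps = {"NS": 0.0, "LS": 0.0, "HS": 0.0}
            amps.update(self.evoked_amplitude_hz)
            return amps
        return dict(PRE_CFA_AMPLITUDES if self.tuning_regime == "pre_cfa"
                    else POST_CFA_AMPLITUDES)


def evoked_kernel(t, rise_s: float = 0.5, decay_s: float = 1.5) -> np.ndarray:
    """Normalized transient: linear rise to 1 over ``rise_s``, then exp decay."""
    t = np.asarray(t, dtype=float)
    k = np.where(t < rise_s, t / rise_s, np.exp(-(t - rise_s) / decay_s))
    return np.where(t < 0, 0.0, k)


def _draw_withdrawal(stimulus: str, cfg: GeneratorConfig, rng: np.random.Generator):
    if stimulus == "NS":
        if rng.random() < cfg.ns_withdrawal_prob:
            return float(np.clip(rng.uniform(2.5, 5.0), 0, 4.999))
        return np.nan
    p = cfg.withdrawal_params[stimulus]
    scale = (p["mean_s"] - p["shift_s"]) / cfg.withdrawal_shape
    lat = p["shift_s"] + rng.gamma(cfg.withdrawal_shape, scale)
    return float(np.clip(lat, 0.05, 4.999))


def _evoked_spike_times(peak_rate: float, cfg: GeneratorConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson on [0, window) with rate peak_rate * k(t), by thinning."""
    if peak_rate <= 0:
        return np.empty(0)
    n = rng.poisson(peak_rate * cfg.window_s)
    cand = rng.uniform(0, cfg.window_s, size=n)
    keep = rng.uniform(size=n) < evoked_kernel(cand, cfg.kernel_rise_s, cfg.kernel_decay_s)
    return cand[keep]


def generate_session(cfg: GeneratorConfig, stimulus_set: list[str],
                     seed: int | None = None, session_id: str = "S0") -> SpikeSession:
    """Simulate one recording session for the given per-trial stimulus labels.

    Baseline spikes are homogeneous Poisson over the whole window; the evoked
    transient is superposed on [0, window) for responsive units, scaled by the
    class amplitude and a per-trial gain.  Withdrawal latencies are drawn so
    HS withdraws faster than LS on average and NS withdraws on <5% of trials.
    """
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    amps = cfg.amplitudes()
    unknown = set(stimulus_set) - set(amps)
    if unknown:
        raise GeneratorError(f"unknown stimulus classes {sorted(unknown)}")

    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                                 size=cfg.n_units))
    responsive = rng.uniform(size=cfg.n_units) < cfg.fraction_responsive
    units = [f"{session_id}_u{i}" for i in range(cfg.n_units)]

    gain_sigma = math.sqrt(math.log1p(cfg.gain_sd ** 2))  # log-normal, mean 1
    trial_rows, spike_rows = [], []
    for trial_id, stim in enumerate(stimulus_set):
        gain = float(rng.lognormal(-gain_sigma ** 2 / 2, gain_sigma)) \
            if cfg.gain_sd > 0 else 1.0
        for u, unit in enumerate(units):
            n_base = rng.poisson(baseline[u] * 2 * cfg.window_s)
            t_base = rng.uniform(-cfg.window_s, cfg.window_s, size=n_base)
            amp = amps[stim] if responsive[u] else 0.0
            t_ev = _evoked_spike_times(gain * amp, cfg, rng)
            for t in np.concatenate([t_base, t_ev]):
                spike_rows.append((unit, trial_id, float(t)))
        trial_rows.append({
            "trial_id": trial_id, "stimulus": stim,
            "withdrawal_latency_s": _draw_withdrawal(stim, cfg, rng),
            "laser_mW": LASER_MW[stim],
            "iti_s": float(max(rng.normal(cfg.iti_mean_s, cfg.iti_sd_s), 1.0)),
        })

    spikes = pd.DataFrame(spike_rows, columns=["unit_id", "trial_id", "t_s"])
    spikes = spikes.sort_values(["unit_id", "trial_id", "t_s"]).reset_index(drop=True)
    session = SpikeSession(session_id=session_id, units=units, spikes=spikes,
                           trials=pd.DataFrame(trial_rows), window_s=cfg.window_s)
    session.validate()
    return session


def single_class_trials(stimulus: str, n_trials: int) -> list[str]:
    return [stimulus] * n_trials


def mixed_trials(classes: tuple[str, str], n_each: int,
                 rng: np.random.Generator) -> list[str]:
    """Randomly interleaved trial labels, equal counts per class."""
    labels = [classes[0]] * n_each + [classes[1]] * n_each
    return list(rng.permutation(labels))


def generate_mixed_session(cfg: GeneratorConfig, classes: tuple[str, str],
                           seed: int, session_id: str = "S0",
                           n_each: int | None = None) -> SpikeSession:
    """A two-class session with randomly interleaved, balanced trials."""
    ss = np.random.SeedSequence(seed).spawn(2)
    order_rng = np.random.default_rng(ss[0])
    labels = mixed_trials(classes, cfg.n_trials_mixed if n_each is None else n_each,
                          order_rng)
    return generate_session(cfg, labels, seed=int(ss[1].generate_state(1)[0] % 2**31),
                            session_id=session_id)


# ------------------------------------------------------ tuning cohorts ------

def calibrate_tuning_noise_sd(slope: float, ls_sd: float, r_squared: float) -> float:
    """Gaussian noise SD giving the requested fitted-vs-observed R^2.

    For y = slope*x + eps, R^2 ~= var(slope*x) / (var(slope*x) + var(eps)),
    so sd(eps) = slope * sd(x) * sqrt((1 - R^2)/R^2).
    """
    if not 0 < r_squared <= 1:
        raise GeneratorError("r_squared must lie in (0, 1]")
    return slope * ls_sd * math.sqrt((1 - r_squared) / r_squared)


def generate_tuning_cohort(n_neurons: int, slope: float, seed: int | None = None,
                           noise_sd: float | None = None,
                           r_squared: float | None = None,
                           ls_log_mean: float = math.log(4.0),
                           ls_log_sd: float = 0.4) -> pd.DataFrame:
    """Draw (ls_peak, hs_peak) pairs with hs = slope * ls + Gaussian noise.

    LS peaks are log-normal (median 4, on the scale of peak z-scored
    responses of strongly driven units).  Either ``noise_sd`` is given
    directly or derived from a target ``r_squared``.
    """
    if slope <= 0:
        raise GeneratorError("slope must be positive")
    if n_neurons < 3:
        raise GeneratorError("need at least 3 neurons")
    if (noise_sd is None) == (r_squared is None):
        raise GeneratorError("give exactly one of noise_sd or r_squared")
    rng = np.random.default_rng(seed)
    ls = np.exp(rng.normal(ls_log_mean, ls_log_sd, size=n_neurons))
    if noise_sd is None:
        noise_sd = calibrate_tuning_noise_sd(slope, float(ls.std(ddof=1)), r_squared)
    if noise_sd < 0:
        raise GeneratorError("noise_sd must be nonnegative")
    hs = slope * ls + rng.normal(0.0, noise_sd, size=n_neurons)
    return pd.DataFrame({"unit_id": [f"n{i}" for i in range(n_neurons)],
                         "ls_peak": ls, "hs_peak": hs})


# --------------------------------------------------------- CPA cohorts ------

def generate_cpa_cohort(cfg: GeneratorConfig, n_animals: int, effect_s: float,
                        seed: int | None = None, group: str = "",
                        paired: tuple[str, str] = ("LS", "NS")) -> list[CPARecord]:
    """Two-chamber occupancy records with a given mean aversion effect.

    Baseline time in the stimulus-paired chamber is Normal(300, baseline SD);
    at test it drops by ``effect_s`` plus noise.  Occupancy of the two
    chambers sums exactly to the 600 s phase duration in both phases.
    """
    if not 0 <= effect_s <= cfg.cpa_phase_s:
        raise GeneratorError("aversion effect must lie within the phase duration")
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    half = cfg.cpa_phase_s / 2
    records = []
    for i in range(n_animals):
        base = float(np.clip(rng.normal(half, cfg.cpa_baseline_sd_s),
                             0.0, cfg.cpa_phase_s))
        noise = rng.normal(0.0, cfg.cpa_test_noise_sd_s) if cfg.cpa_test_noise_sd_s > 0 else 0.0
        test = float(np.clip(base - effect_s + noise, 0.0, cfg.cpa_phase_s))
        records.append(CPARecord(
            animal_id=f"{group or 'a'}{i}", group=group,
            chambers={
                "A": ChamberOccupancy(base, test, paired[0]),
                "B": ChamberOccupancy(cfg.cpa_phase_s - base,
                                      cfg.cpa_phase_s - test, paired[1]),
            }))
    return records


# -------------------------------------------------- up-down sequences -------

def simulate_updown_sequence(true_threshold_g: float, seed: int | None = None,
                             response_sd_log: float = 0.0,
                             filaments_g: tuple = None,
                             start_g: float = None,
                             max_len: int = 20):
    """Simulate an up-down staircase for an animal with a known threshold.

    The animal withdraws when the applied force exceeds its threshold,
    optionally blurred by a log-normal perceptual scatter
    (``response_sd_log`` in log10 units).  Returns a
    :class:`~paincode.behavior.VonFreySequence`.
    """
    from .behavior import FILAMENTS_G, START_G, VonFreySequence
    fil = FILAMENTS_G if filaments_g is None else tuple(filaments_g)
    start = START_G if start_g is None else start_g
    rng = np.random.default_rng(seed)
    idx = fil.index(start)
    responses = []
    reversal_at = None
    while len(responses) < max_len:
        g = fil[idx]
        thr = true_threshold_g
        if response_sd_log > 0:
            thr = 10 ** (math.log10(true_threshold_g)
                         + rng.normal(0.0, response_sd_log))
        r = "X" if g >= thr else "O"
        responses.append(r)
        if reversal_at is None and len(responses) > 1 and r != responses[0]:
            reversal_at = len(responses) - 1
        if reversal_at is not None and len(responses) >= reversal_at + 1 + 4:
            break
        nxt = idx + (-1 if r == "X" else +1)
        if nxt < 0 or nxt >= len(fil):
            break       # pinned at a boundary: clamped estimate downstream
        idx = nxt
    return VonFreySequence("".join(responses), filaments_g=fil, start_g=start)
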