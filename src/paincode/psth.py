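"""Trial-aligned spike binning and baseline-normalized (z-scored) PSTHs.

The peristimulus time histogram is computed on a symmetric window around
stimulus onset (default 5 s each side) with 200 ms half-open bins ``[t, t+d)``;
a spike exactly at onset falls in the first post-stimulus bin.  The z-scored
rate of a unit is

    Z(bin) = (FR(bin) - mean(FR_b)) / SD(FR_b)

where ``FR`` is the trial-averaged rate per bin and ``FR_b`` are the
pre-stimulus (baseline) bins of that trial-averaged rate.  By construction the
baseline bins of ``Z`` then have sample mean 0 and sample SD 1.  An
alternative reading, pooling the SD across per-trial baseline rates, is
available via ``baseline_sd_mode="trials"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SpikeSession


class PSTHError(ValueError):
    pass


@dataclass
class CountTensor:
    """Exact spike counts indexed (unit, trial, bin) over ``[-window, +window)``."""

    counts: np.ndarray          # (U, T, B) integer counts
    bin_size_s: float
    window_s: float
    units: list[str]
    trial_ids: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def n_baseline_bins(self) -> int:
        return self.n_bins // 2

    @property
    def bin_edges(self) -> np.ndarray:
        return -self.window_s + self.bin_size_s * np.arange(self.n_bins + 1)


@dataclass
class PSTHMatrix:
    """Per-unit trial-averaged rates with baseline statistics and z-scores.

    ``z`` is NaN for units flagged ``degenerate`` (zero baseline variability);
    such units are excluded from downstream classification.
    """

    units: list[str]
    z: np.ndarray               # (U, B)
    fr: np.ndarray              # (U, B) trial-averaged rate, Hz
    fr_sem: np.ndarray          # (U, B) SE of per-trial rate across trials, Hz
    fr_b_mean: np.ndarray       # (U,) baseline mean rate, Hz
    fr_b_sd: np.ndarray         # (U,) baseline rate SD, Hz
    degenerate: np.ndarray      # (U,) bool
    bin_size_s: float
    window_s: float
    n_trials: int

    @property
    def n_baseline_bins(self) -> int:
        return self.z.shape[1] // 2

    def post_z(self) -> np.ndarray:
        """Z-scores of the post-stimulus bins, shape (U, B/2)."""
        return self.z[:, self.n_baseline_bins:]


def bin_counts(session: SpikeSession, bin_size_s: float = 0.2,
               window_s: float | None = None) -> CountTensor:
    """Bin a session's spikes into exact (unit, trial, bin) counts.

    Bins are half-open ``[t, t + bin_size)``; the bin size must divide the
    window into an integer number of bins on each side.
    """
    if window_s is None:
        window_s = session.window_s
    n_side = window_s / bin_size_s
    if abs(n_side - round(n_side)) > 1e-9:
        raise PSTHError(f"bin size {bin_size_s} does not divide window {window_s}")
    n_side = int(round(n_side))
    n_bins = 2 * n_side
    if session.n_trials == 0:
        raise PSTHError(f"session {session.session_id} has no trials")

    units = list(session.units)
    trial_ids = session.trials["trial_id"].to_numpy()
    u_index = {u: i for i, u in enumerate(units)}
    t_index = {t: i for i, t in enumerate(trial_ids)}

    counts = np.zeros((len(units), len(trial_ids), n_bins), dtype=np.int64)
    if len(session.spikes):
        sp = session.spikes
        t = sp["t_s"].to_numpy(dtype=float)
        if np.any((t < -window_s) | (t >= window_s)):
            raise PSTHError("spike times outside the analysis window")
        b = np.floor((t + window_s) / bin_size_s).astype(np.int64)
        b = np.minimum(b, n_bins - 1)   # guard exact upper edge under fp round-off
        ui = sp["unit_id"].map(u_index).to_numpy()
        ti = sp["trial_id"].map(t_index).to_numpy()
        if np.any(np.isnan(ui.astype(float))) or np.any(np.isnan(ti.astype(float))):
            raise PSTHError("spikes reference unknown units or trials")
        np.add.at(counts, (ui.astype(np.int64), ti.astype(np.int64), b), 1)
    return CountTensor(counts=counts, bin_size_s=bin_size_s, window_s=window_s,
                       units=units, trial_ids=trial_ids)


def zscore_psth(counts: CountTensor, baseline_sd_mode: str = "bins",
                baseline_stats: tuple[np.ndarray, np.ndarray] | None = None
                ) -> PSTHMatrix:
    """Baseline-normalize trial-averaged rates into a z-scored PSTH.

    Units with zero baseline variability are flagged degenerate and their
    z-scores set to NaN rather than propagating infinities.

    ``baseline_stats`` optionally supplies per-unit ``(mean, sd)`` of the
    baseline rate computed elsewhere — e.g. from all trials of a session when
    z-scoring one stimulus class of it — instead of re-estimating them from
    ``counts``.
    """
    c = counts.counts
    U, T, B = c.shape
    if T < 2:
        raise PSTHError("z-scoring requires at least 2 trials")
    nb = counts.n_baseline_bins
    if nb < 2:
        raise PSTHError("z-scoring requires at least 2 baseline bins")
    dt = counts.bin_size_s

    rates = c / dt                              # per-trial rates, Hz
    fr = rates.mean(axis=1)                     # (U, B)
    fr_sem = rates.std(axis=1, ddof=1) / np.sqrt(T)

    if baseline_stats is not None:
        fr_b_mean = np.asarray(baseline_stats[0], dtype=float)
        fr_b_sd = np.asarray(baseline_stats[1], dtype=float)
    elif baseline_sd_mode == "bins":
        fr_b_mean = fr[:, :nb].mean(axis=1)
        fr_b_sd = fr[:, :nb].std(axis=1, ddof=1)
    elif baseline_sd_mode == "trials":
        base = rates[:, :, :nb].reshape(U, -1)
        fr_b_mean = base.mean(axis=1)
        fr_b_sd = base.std(axis=1, ddof=1)
    else:
        raise PSTHError("baseline_sd_mode must be 'bins' or 'trials'")

    degenerate = fr_b_sd <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (fr - fr_b_mean[:, None]) / fr_b_sd[:, None]
    z[degenerate] = np.nan
    return PSTHMatrix(units=list(counts.units), z=z, fr=fr, fr_sem=fr_sem,
                      fr_b_mean=fr_b_mean, fr_b_sd=fr_b_sd, degenerate=degenerate,
                      bin_size_s=dt, window_s=counts.window_s, n_trials=T)


def filter_low_rate_units(session: SpikeSession, min_peak_rate_hz: float = 1.0,
                          bin_size_s: float = 0.2) -> SpikeSession:
    """Drop units whose trial-averaged peak rate never reaches the threshold.

    The peak is the maximum over all bins (200 ms, full window) of the
    trial-averaged firing rate; units below ``min_peak_rate_hz`` everywhere
    are excluded from analysis.
    """
    counts = bin_counts(session, bin_size_s=bin_size_s)
    peak = (counts.counts.mean(axis=1) / bin_size_s).max(axis=1)
    keep = [u for u, p in zip(counts.units, peak) if p >= min_peak_rate_hz]
    return session.subset_units(keep)


def session_psth(session: SpikeSession, stimulus: str | None = None,
                 bin_size_s: float = 0.2, baseline_sd_mode: str = "bins",
                 baseline_from: str = "session") -> PSTHMatrix:
    """Convenience: bin (optionally one stimulus class) and z-score.

    With ``baseline_from="session"`` (default) the baseline statistics come
    from all trials of the session even when ``stimulus`` restricts the PSTH
    to one class, so the classes of a mixed session share one normalizer;
    pre-stimulus activity does not depend on the upcoming stimulus, and
    independent noisy normalizers would dilute between-class comparisons.
    ``baseline_from="class"`` re-estimates the baseline from the selected
    trials only.
    """
    if baseline_from not in ("session", "class"):
        raise PSTHError("baseline_from must be 'session' or 'class'")
    stats = None
    if stimulus is not None:
        if baseline_from == "session":
            full = zscore_psth(bin_counts(session, bin_size_s=bin_size_s),
                               baseline_sd_mode=baseline_sd_mode)
            stats = (full.fr_b_mean, full.fr_b_sd)
        session = session.subset_trials(session.trials_for(stimulus))
    return zscore_psth(bin_counts(session, bin_size_s=bin_size_s),
                       baseline_sd_mode=baseline_sd_mode, baseline_stats=stats)
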