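"""Responsive-unit classification and intensity-coding identification.

A unit counts as pain-responsive when two threshold criteria hold on its
post-stimulus z-scored PSTH:

1. at least two post-stimulus bins reach ``|Z| >= 2.33``, and
2. (checked only if 1 passes) at least two post-stimulus bins have a lower
   bound ``Z - Z_SEM > 1.645``,

where ``Z_SEM(bin) = FR_SEM(bin) / SD(FR_b)`` expresses the across-trial
standard error of the bin rate in baseline-SD units.  The conjunction of the
two two-bin criteria keeps the false-positive rate of a stationary unit well
below 5%.

Intensity-coding units are the subset of responsive units whose per-trial
peak response is larger under the high- than the low-intensity stimulus by a
paired t-test.  When LS and HS trials come from separate recordings there is
no natural trial pairing; trials are paired by recording order by default
(``pairing="rank"`` pairs sorted responses instead, which sharpens power for
a true amplitude difference but is anti-conservative under the null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import SpikeSession
from .psth import CountTensor, PSTHMatrix, bin_counts, zscore_psth


class ResponsiveError(ValueError):
    pass


@dataclass
class ResponsivenessResult:
    unit_id: str
    is_responsive: bool
    indeterminate: bool             # degenerate baseline: never responsive
    z_per_bin: np.ndarray           # post-stimulus z
    z_sem_per_bin: np.ndarray       # post-stimulus Z_SEM
    bins_criterion_1: np.ndarray    # post-bin indices with |z| >= thr1
    bins_criterion_2: np.ndarray    # post-bin indices with z - z_sem > thr2


@dataclass
class IntensityCodingResult:
    unit_id: str
    hs_gt_ls: bool
    t_statistic: float
    p_value: float
    ls_mean_peak: float
    hs_mean_peak: float
    n_pairs: int


def compute_z_sem(psth: PSTHMatrix) -> np.ndarray:
    """Across-trial SE of the bin rate in baseline-SD units, shape (U, B).

    NaN for degenerate-baseline units.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        z_sem = psth.fr_sem / psth.fr_b_sd[:, None]
    z_sem[psth.degenerate] = np.nan
    return z_sem


def classify_responsive(psth: PSTHMatrix, z_sem: np.ndarray | None = None,
                        thresholds: tuple[float, float] = (2.33, 1.645),
                        min_bins: int = 2) -> list[ResponsivenessResult]:
    """Apply the two-part threshold criterion to every unit of a PSTH."""
    if z_sem is None:
        z_sem = compute_z_sem(psth)
    thr_abs, thr_lower = thresholds
    nb = psth.n_baseline_bins
    out: list[ResponsivenessResult] = []
    for i, unit in enumerate(psth.units):
        z_post = psth.z[i, nb:]
        zs_post = z_sem[i, nb:]
        if psth.degenerate[i]:
            out.append(ResponsivenessResult(unit, False, True, z_post, zs_post,
                                            np.array([], int), np.array([], int)))
            continue
        c1 = np.flatnonzero(np.abs(z_post) >= thr_abs)
        if len(c1) >= min_bins:
            c2 = np.flatnonzero((z_post - zs_post) > thr_lower)
        else:
            c2 = np.array([], dtype=int)
        responsive = len(c1) >= min_bins and len(c2) >= min_bins
        out.append(ResponsivenessResult(unit, responsive, False, z_post, zs_post, c1, c2))
    return out


def per_trial_peak_z(session: SpikeSession, stimulus: str, bin_size_s: float = 0.2,
                     baseline_sd_mode: str = "bins") -> tuple[list[str], np.ndarray]:
    """Per-trial peak post-stimulus response of each unit, in baseline-SD units.

    Each trial's binned rates are normalized with the unit's session-level
    baseline statistics and the maximum over post-stimulus bins is taken;
    returns (units, array of shape (U, T)).  Degenerate units yield NaN.

    Baseline statistics are pooled over *all* trials of the session, not just
    the requested stimulus class: pre-stimulus activity does not depend on
    the upcoming stimulus, and a shared normalizer keeps paired comparisons
    between two classes of the same session calibrated (a class-specific
    noisy SD estimate would shift every trial of that class coherently).
    """
    full_psth = zscore_psth(bin_counts(session, bin_size_s=bin_size_s),
                            baseline_sd_mode=baseline_sd_mode)
    sub = session.subset_trials(session.trials_for(stimulus))
    counts = bin_counts(sub, bin_size_s=bin_size_s)
    nb = counts.n_baseline_bins
    rates = counts.counts[:, :, nb:] / bin_size_s       # (U, T, B/2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_trial = (rates - full_psth.fr_b_mean[:, None, None]) \
            / full_psth.fr_b_sd[:, None, None]
    z_trial[full_psth.degenerate] = np.nan
    return list(counts.units), z_trial.max(axis=2)


def identify_intensity_coding(responsive_units: list[str], ls_session: SpikeSession,
                              hs_session: SpikeSession, alpha: float = 0.05,
                              pairing: str = "index", bin_size_s: float = 0.2,
                              ) -> list[IntensityCodingResult]:
    """Flag responsive units firing more to HS than LS (paired t-test).

    Only units present in both sessions are testable; unequal trial counts
    are truncated to the common length.
    """
    if pairing not in ("rank", "index"):
        raise ResponsiveError("pairing must be 'rank' or 'index'")
    ls_units, ls_peaks = per_trial_peak_z(ls_session, "LS", bin_size_s)
    hs_units, hs_peaks = per_trial_peak_z(hs_session, "HS", bin_size_s)
    ls_ix = {u: i for i, u in enumerate(ls_units)}
    hs_ix = {u: i for i, u in enumerate(hs_units)}

    results: list[IntensityCodingResult] = []
    for unit in responsive_units:
        if unit not in ls_ix or unit not in hs_ix:
            continue
        ls = ls_peaks[ls_ix[unit]]
        hs = hs_peaks[hs_ix[unit]]
        if np.any(np.isnan(ls)) or np.any(np.isnan(hs)):
            continue
        n = min(len(ls), len(hs))
        if n < 2:
            continue
        ls, hs = ls[:n].copy(), hs[:n].copy()
        if pairing == "rank":
            ls.sort()
            hs.sort()
        if np.allclose(hs - ls, (hs - ls)[0]):
            # zero-variance differences: degenerate t-test
            d = float(np.mean(hs - ls))
            t_stat, p = (np.inf if d > 0 else -np.inf if d < 0 else 0.0), (0.0 if d > 0 else 1.0)
        else:
            t_stat, p = stats.ttest_rel(hs, ls, alternative="greater")
        results.append(IntensityCodingResult(
            unit_id=unit, hs_gt_ls=bool(p < alpha and np.mean(hs) > np.mean(ls)),
            t_statistic=float(t_stat), p_value=float(p),
            ls_mean_peak=float(np.mean(ls)), hs_mean_peak=float(np.mean(hs)),
            n_pairs=int(n)))
    return results
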