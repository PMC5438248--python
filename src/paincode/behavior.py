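"""Behavioral quantification: place-aversion scores, withdrawal summaries,
and the up-down 50% mechanical withdrawal threshold.

Conditioned place aversion (CPA)
    Two chambers, three 10-min (600 s) phases.  Animals spending < 100 s or
    > 500 s in either main chamber at baseline show too strong an innate side
    bias and are excluded.  The CPA score of a stimulus-paired chamber is
    ``baseline_s - test_s``: positive values mean the animal avoided the
    chamber after conditioning, i.e. found the paired stimulus aversive.

Up-down 50% threshold (von Frey)
    An adaptive staircase over a calibrated filament set with roughly
    logarithmic force spacing, starting at 2.55 g: a withdrawal response (X)
    steps down, no response (O) steps up, and testing continues for four
    stimuli past the first direction change.  The 50% threshold is
    ``10**(x_f + k*delta) / 10**4`` grams, where ``x_f = log10(10^4 * g_f)``
    is the log-unit value of the final filament, ``delta`` the mean log step
    of the set, and ``k`` a pattern-dependent factor.  Here ``k`` is derived
    from the sequence's maximum-likelihood threshold under a cumulative-normal
    response model with scale ``delta`` (the model the tabulated factors of
    the classical staircase method approximate), so the estimator is defined
    for every valid sequence; monotone all-X / all-O runs clamp to the ends
    of the filament set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import CPARecord

FILAMENTS_G = (0.45, 0.75, 1.20, 2.55, 4.40, 6.10, 10.50, 15.10)
START_G = 2.55
POST_REVERSAL_STIMULI = 4       # stimuli applied after the first reversal


class BehaviorError(ValueError):
    pass


# ---------------------------------------------------------------- CPA -------

def filter_cpa_baseline(records: list[CPARecord], lo: float = 100.0,
                        hi: float = 500.0) -> tuple[list[CPARecord],
                                                    list[tuple[CPARecord, str]]]:
    """Split records into (kept, excluded-with-reason) by baseline side bias."""
    kept, excluded = [], []
    for rec in records:
        if len(rec.chambers) != 2:
            raise BehaviorError(
                f"animal {rec.animal_id}: expected 2 chambers, found {len(rec.chambers)}")
        reasons = [
            f"chamber {name}: baseline {occ.baseline_s:.0f} s outside [{lo:.0f}, {hi:.0f}]"
            for name, occ in rec.chambers.items()
            if occ.baseline_s < lo or occ.baseline_s > hi
        ]
        if reasons:
            excluded.append((rec, "; ".join(reasons)))
        else:
            kept.append(rec)
    return kept, excluded


def cpa_score(record: CPARecord, target_chamber: str) -> float:
    """Aversion score of a chamber: baseline minus test occupancy (seconds)."""
    if target_chamber not in record.chambers:
        raise BehaviorError(
            f"animal {record.animal_id} has no chamber {target_chamber!r}")
    occ = record.chambers[target_chamber]
    return float(occ.baseline_s - occ.test_s)


def cpa_score_for_stimulus(record: CPARecord, stimulus: str) -> float:
    """CPA score of the chamber paired with ``stimulus``."""
    return cpa_score(record, record.chamber_for(stimulus))


def summarize_cpa(records: list[CPARecord], stimulus: str) -> dict:
    scores = np.array([cpa_score_for_stimulus(r, stimulus) for r in records])
    return {
        "stimulus": stimulus, "n": len(scores),
        "score_mean_s": float(scores.mean()),
        "score_sem_s": float(scores.std(ddof=1) / np.sqrt(len(scores)))
        if len(scores) > 1 else 0.0,
    }


def compare_groups(a, b, paired: bool = False) -> dict:
    """Thin t-test reporting helper for group score comparisons."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b)
    return {"t_statistic": float(t), "p_value": float(p),
            "mean_a": float(a.mean()), "mean_b": float(b.mean())}


# --------------------------------------------------- up-down threshold ------

@dataclass
class VonFreySequence:
    """An up-down staircase outcome: X = withdrawal, O = no response.

    The filament actually applied at each step is implied by the response
    string: start at ``start_g``, step down after X, up after O, pinned at
    the ends of the set.
    """

    responses: str
    filaments_g: tuple[float, ...] = FILAMENTS_G
    start_g: float = START_G

    def __post_init__(self) -> None:
        if not self.responses or set(self.responses) - {"X", "O"}:
            raise BehaviorError("responses must be a non-empty string over {X, O}")
        if self.start_g not in self.filaments_g:
            raise BehaviorError(f"start filament {self.start_g} g not in the set")
        if list(self.filaments_g) != sorted(self.filaments_g):
            raise BehaviorError("filament set must be sorted ascending")

    def applied_indices(self) -> list[int]:
        """Replay the staircase: the filament index applied at each response."""
        idx = self.filaments_g.index(self.start_g)
        out = []
        for r in self.responses:
            out.append(idx)
            step = -1 if r == "X" else +1
            idx = min(max(idx + step, 0), len(self.filaments_g) - 1)
        return out

    def is_terminated(self) -> bool:
        """True if the sequence ran 4 stimuli past the first reversal."""
        first = self.responses[0]
        for i, r in enumerate(self.responses):
            if r != first:
                return len(self.responses) >= i + 1 + POST_REVERSAL_STIMULI
        return False

    def hit_boundary(self) -> bool:
        """Monotone run pinned at an end of the filament set."""
        idxs = self.applied_indices()
        if all(r == "X" for r in self.responses):
            return idxs[-1] == 0
        if all(r == "O" for r in self.responses):
            return idxs[-1] == len(self.filaments_g) - 1
        return False


def _log_units(g: np.ndarray | float) -> np.ndarray | float:
    # conventional log-unit scale of the filament set: log10 of force in 0.1 mg
    return np.log10(np.asarray(g, dtype=float) * 1e4)


def _ml_threshold_log(x: np.ndarray, responses: np.ndarray, delta: float) -> float:
    """ML location of a cumulative-normal response curve with scale delta."""
    def nll(mu: float) -> float:
        p = stats.norm.cdf((x - mu) / delta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(responses * np.log(p) + (1 - responses) * np.log1p(-p)))

    lo, hi = x.min() - 6 * delta, x.max() + 6 * delta
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def updown_50pct_threshold(seq: VonFreySequence) -> float:
    """50% withdrawal threshold in grams from an up-down response sequence.

    Monotone sequences that run off the end of the filament set clamp to the
    minimum (all responses) or maximum (no responses) filament; otherwise the
    estimate is ``10**(x_f + k*delta)/10**4`` with the pattern factor ``k``
    obtained by maximum likelihood (see module docstring), clamped to the
    range of the set.
    """
    fil = np.asarray(seq.filaments_g, dtype=float)
    if seq.hit_boundary():
        return float(fil[0] if seq.responses[0] == "X" else fil[-1])
    if len(set(seq.responses)) < 2:
        raise BehaviorError(
            "monotone sequence did not reach a filament-set boundary: apply more "
            "stimuli (or continue to the boundary) before estimating")
    idxs = seq.applied_indices()
    x = _log_units(fil)[idxs]
    responses = np.array([1.0 if r == "X" else 0.0 for r in seq.responses])
    delta = float(np.mean(np.diff(_log_units(fil))))
    mu = _ml_threshold_log(np.asarray(x), responses, delta)
    grams = 10.0 ** mu / 1e4
    return float(np.clip(grams, fil[0], fil[-1]))


def updown_k_factor(seq: VonFreySequence) -> float:
    """The pattern factor k with threshold = 10**(x_f + k*delta)/10**4."""
    fil = np.asarray(seq.filaments_g, dtype=float)
    delta = float(np.mean(np.diff(_log_units(fil))))
    x_f = float(_log_units(fil[seq.applied_indices()[-1]]))
    thr = updown_50pct_threshold(seq)
    return (float(_log_units(thr)) - x_f) / delta


# ------------------------------------------------ withdrawal summaries ------

def withdrawal_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-stimulus withdrawal fraction and latency mean +/- SEM.

    ``trials`` needs columns ``stimulus`` and ``withdrawal_latency_s`` (NaN =
    no withdrawal within the 5 s stimulus).  Empty classes are omitted.
    """
    if "stimulus" not in trials or "withdrawal_latency_s" not in trials:
        raise BehaviorError("trials need 'stimulus' and 'withdrawal_latency_s' columns")
    rows = []
    for stim, sub in trials.groupby("stimulus", sort=True):
        lat = pd.to_numeric(sub["withdrawal_latency_s"], errors="coerce")
        withdrew = lat.notna()
        vals = lat[withdrew].to_numpy(float)
        rows.append({
            "stimulus": stim,
            "n_trials": len(sub),
            "n_withdrawals": int(withdrew.sum()),
            "withdrawal_fraction": float(withdrew.mean()),
            "latency_mean_s": float(vals.mean()) if len(vals) else np.nan,
            "latency_sem_s": float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def withdrawal_velocity(height_m, time_to_height_s) -> np.ndarray:
    """Withdrawal velocity per event: peak paw height over time to reach it."""
    h = np.asarray(height_m, dtype=float)
    t = np.asarray(time_to_height_s, dtype=float)
    if np.any(t <= 0):
        raise BehaviorError("time to peak height must be positive")
    return h / t
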