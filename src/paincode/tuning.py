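"""Intensity tuning curves: robust regression of HS peaks on LS peaks.

Across neurons that fire more to the high- than the low-intensity stimulus,
the relation between the peak z-scored response under LS (x) and under HS (y)
summarizes intensity discrimination: a slope well above 1 means the
population amplifies the distinction between the two intensities, a slope
near 1 means the tuning has flattened.  The line is fit by iteratively
reweighted least squares with a Tukey bisquare M-estimator (tuning constant
4.685, the conventional 95%-efficiency choice), and two fitted slopes are
compared with a t statistic

    t = (b1 - b2) / sqrt(se1^2 + se2^2),   df = n1 + n2 - 4.

R^2 of a robust fit is not uniquely defined; it is reported as the squared
Pearson correlation between fitted and observed HS peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .psth import PSTHMatrix


class TuningError(ValueError):
    pass


@dataclass
class TuningFit:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    n: int


@dataclass
class SlopeComparison:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float


def extract_peak_pairs(psth_ls: PSTHMatrix, psth_hs: PSTHMatrix) -> pd.DataFrame:
    """Per-unit (ls_peak, hs_peak) of peak post-stimulus z, keeping hs > ls.

    Units missing from either condition or with a degenerate baseline in
    either are skipped; only units responding more strongly to HS than LS
    enter the tuning-fit population.
    """
    hs_index = {u: i for i, u in enumerate(psth_hs.units)}
    rows = []
    for i, unit in enumerate(psth_ls.units):
        j = hs_index.get(unit)
        if j is None or psth_ls.degenerate[i] or psth_hs.degenerate[j]:
            continue
        ls_peak = float(np.max(psth_ls.post_z()[i]))
        hs_peak = float(np.max(psth_hs.post_z()[j]))
        if hs_peak > ls_peak:
            rows.append({"unit_id": unit, "ls_peak": ls_peak, "hs_peak": hs_peak})
    return pd.DataFrame(rows, columns=["unit_id", "ls_peak", "hs_peak"])


def fit_tuning_slope(ls_peak, hs_peak, tuning_constant: float = 4.685) -> TuningFit:
    """Robust (IRLS, Tukey bisquare) linear fit of HS peaks on LS peaks."""
    x = np.asarray(ls_peak, dtype=float)
    y = np.asarray(hs_peak, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise TuningError("ls_peak and hs_peak must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise TuningError(f"need at least 3 pairs to fit a line (have {n})")
    if np.ptp(x) == 0:
        raise TuningError("all LS peaks identical: singular design")
    exog = sm.add_constant(x)
    model = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=tuning_constant))
    res = model.fit()
    fitted = res.fittedvalues
    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        r2 = 1.0 if np.allclose(fitted, y) else 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    return TuningFit(slope=float(res.params[1]), slope_se=float(res.bse[1]),
                     intercept=float(res.params[0]), intercept_se=float(res.bse[0]),
                     r_squared=r2, n=n)


def fit_tuning_from_pairs(pairs: pd.DataFrame, **kwargs) -> TuningFit:
    return fit_tuning_slope(pairs["ls_peak"].to_numpy(),
                            pairs["hs_peak"].to_numpy(), **kwargs)


def compare_slopes(fit_a: TuningFit, fit_b: TuningFit) -> SlopeComparison:
    """Two-sided t-test for equality of two independently fitted slopes."""
    se = float(np.hypot(fit_a.slope_se, fit_b.slope_se))
    df = fit_a.n + fit_b.n - 4
    if df < 1:
        raise TuningError("not enough observations to compare slopes")
    diff = fit_a.slope - fit_b.slope
    if se == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / se
        p = float(2 * stats.t.sf(abs(t), df))
    return SlopeComparison(t_statistic=float(t), degrees_of_freedom=int(df),
                           p_value=p)
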