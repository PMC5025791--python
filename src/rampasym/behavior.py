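"""Learning-curve quantification for the sound-conditioning tasks.

Sound salience is probed through learning speed: the ratio of post- to
pre-stimulus licks in a head-fixed reward-association task, and the rise
duration of a sigmoid fitted to the go/no-go discrimination learning curve
(the number of trials to go from 20% to 80% of plateau performance above
the 50% chance level), compared across training groups with a two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .synth import LearningCurve

__all__ = ["lick_ratio", "rise_duration", "fit_learning_curve", "compare_groups"]

log = logging.getLogger(__name__)


def lick_ratio(records: pd.DataFrame, by: str = "day") -> pd.Series:
    """Sum(post-stimulus licks) / sum(pre-stimulus licks) per aggregation unit.

    ``records`` needs columns ``pre`` and ``post`` (per-trial lick counts)
    plus the grouping column (default ``day``).  Units with zero
    pre-stimulus licks yield NaN (logged).
    """
    g = records.groupby(by)[["pre", "post"]].sum()
    ratio = pd.Series(np.nan, index=g.index, name="lick_ratio")
    ok = g["pre"] > 0
    if not ok.all():
        log.warning("zero pre-stimulus licks in %d unit(s); ratio undefined",
                    int((~ok).sum()))
    ratio[ok] = g.loc[ok, "post"] / g.loc[ok, "pre"]
    return ratio


def _logistic(t, plateau, k, t0):
    return 0.5 + (plateau - 0.5) / (1.0 + np.exp(-k * (t - t0)))


def fit_learning_curve(curve: LearningCurve) -> dict:
    """Least-squares logistic fit 0.5 + (plateau-0.5)/(1+exp(-k(t-t0)))."""
    t = curve.trial_index
    y = np.asarray(curve.performance, float)
    p0 = (max(y.max(), 0.55), 4.0 / max(t.max(), 1.0), t.mean())
    bounds = ([0.5, 1e-6, -t.max()], [1.0, np.inf, 2 * t.max()])
    popt, _ = curve_fit(_logistic, t, y, p0=p0, bounds=bounds, maxfev=20000)
    plateau, k, t0 = popt
    return {"plateau": float(plateau), "k": float(k), "t0": float(t0)}


def rise_duration(curve: LearningCurve, min_effect: float = 0.05) -> float:
    """Trials to rise from 20% to 80% of plateau-above-chance: 2 ln(4) / k.

    Curves whose fitted plateau sits within ``min_effect`` of chance never
    leave chance performance; their rise duration is undefined (NaN).
    """
    try:
        fit = fit_learning_curve(curve)
    except RuntimeError as err:
        log.warning("logistic fit failed: %s", err)
        return np.nan
    if fit["plateau"] - curve.chance < min_effect:
        return np.nan
    return 2.0 * np.log(4.0) / fit["k"]


def compare_groups(rises_a: np.ndarray, rises_b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov p-value on individual rise durations."""
    a = np.asarray(rises_a, float)
    b = np.asarray(rises_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 rise durations per group")
    return float(stats.ks_2samp(a, b).pvalue)
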