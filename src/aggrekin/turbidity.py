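"""Bulk lag-phase estimation from turbidity kinetics.

The lag of a replicate curve is the time where the tangent at the point
of maximum smoothed slope crosses the pre-growth baseline. A simpler
threshold-crossing estimator (first time above 5% of the rise) is
available as an alternative. Conditions are compared against a control
with two-sided Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from aggrekin.kinetics import welch_t_test

MIN_REPLICATES_FOR_SUMMARY = 3


class NoGrowthError(ValueError):
    """The curve never rises above its baseline."""


@dataclass
class LagPhaseEstimate:
    condition: str
    replicate_lags_min: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_lags_min))

    @property
    def sd(self) -> float:
        if len(self.replicate_lags_min) < 2:
            return 0.0
        return float(np.std(self.replicate_lags_min, ddof=1))


def estimate_lag(
    time_min: np.ndarray,
    absorbance: np.ndarray,
    method: str = "tangent",
    threshold_frac: float = 0.05,
) -> float:
    """Lag time (min) of a single turbidity curve.

    tangent (default)
        Baseline = mean of pre-growth points (before the signal exceeds
        baseline + ``threshold_frac`` of the full rise); slope smoothed
        by centered differences; lag = intersection of the tangent at
        the maximum-slope point with the baseline.
    threshold
        First time the signal exceeds baseline + ``threshold_frac`` of
        the full rise (linearly interpolated).
    """
    t = np.asarray(time_min, float)
    y = np.asarray(absorbance, float)
    if len(t) < 5:
        raise ValueError("need at least 5 points")
    order = np.argsort(t)
    t, y = t[order], y[order]

    rise = y.max() - y.min()
    if rise <= 0:
        raise NoGrowthError("signal never rises above baseline")
    onset_level = y.min() + threshold_frac * rise
    pre = np.flatnonzero(y > onset_level)
    onset_idx = pre[0] if len(pre) else len(t)
    baseline = float(y[:onset_idx].mean()) if onset_idx > 0 else float(y[0])

    if method == "threshold":
        level = baseline + threshold_frac * (y.max() - baseline)
        above = np.flatnonzero(y >= level)
        if len(above) == 0:
            raise NoGrowthError("signal never crosses the threshold")
        i = above[0]
        if i == 0:
            return float(t[0])
        f = (level - y[i - 1]) / (y[i] - y[i - 1])
        return float(t[i - 1] + f * (t[i] - t[i - 1]))
    if method != "tangent":
        raise ValueError(f"unknown method: {method!r}")

    slope = np.gradient(y, t)  # centered 3-point differences
    i = int(np.argmax(slope))
    if slope[i] <= 0:
        raise NoGrowthError("no positive slope found")
    lag = t[i] - (y[i] - baseline) / slope[i]
    return float(np.clip(lag, t[0], t[-1]))


def estimate_lags(
    dataset: pd.DataFrame, method: str = "tangent"
) -> dict[str, LagPhaseEstimate]:
    """Per-replicate lag estimates from a long-format turbidity table.

    Expects columns ``condition``, ``replicate``, ``time_min``,
    ``absorbance``. Warns if a condition has fewer than three
    replicates.
    """
    out = {}
    for condition, grp in dataset.groupby("condition", sort=False):
        lags = []
        for _, rep in grp.groupby("replicate", sort=True):
            lags.append(
                estimate_lag(
                    rep["time_min"].to_numpy(),
                    rep["absorbance"].to_numpy(),
                    method=method,
                )
            )
        if len(lags) < MIN_REPLICATES_FOR_SUMMARY:
            warnings.warn(
                f"condition {condition!r} has only {len(lags)} replicate(s); "
                "summary statistics need at least three",
                stacklevel=2,
            )
        out[str(condition)] = LagPhaseEstimate(str(condition), np.asarray(lags))
    return out


def compare_conditions(
    estimates: dict[str, LagPhaseEstimate], control: str
) -> pd.DataFrame:
    """Welch t-test of each condition's lag distribution against control.

    Returns a frame with mean, SD, n, t and two-sided p per condition
    (control row included with t = 0, p = 1).
    """
    if control not in estimates:
        raise ValueError(f"control condition {control!r} not present")
    ctrl = estimates[control].replicate_lags_min
    rows = []
    for name, est in estimates.items():
        if name == control:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = welch_t_test(est.replicate_lags_min, ctrl)
        rows.append(
            {
                "condition": name,
                "n": len(est.replicate_lags_min),
                "mean_lag_min": est.mean,
                "sd_lag_min": est.sd,
                "t_vs_control": t_stat,
                "p_vs_control": p,
            }
        )
    return pd.DataFrame(rows)
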