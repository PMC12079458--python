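"""Per-aggregate growth-rate fitting and condition-level statistics.

Growth curves (area vs time) are fit with ordinary least squares:
single-phase growth as one line over the growth phase, anisotropic
growth as a continuous two-segment piecewise line whose changepoint is
found by exhaustive search over the observed time points. Terminated
growth is detected from rolling-window slopes. Rates are reported in
nm²/s; condition summaries report mean ± SE per archetype and Welch
t-tests between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class FitError(ValueError):
    pass


@dataclass
class GrowthCurve:
    """Area-vs-time series for one aggregate (times s, areas nm²)."""

    times_s: np.ndarray
    areas_nm2: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, float)
        self.areas_nm2 = np.asarray(self.areas_nm2, float)
        if self.times_s.shape != self.areas_nm2.shape:
            raise ValueError("times and areas must have equal length")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.areas_nm2) and (
            np.any(self.areas_nm2 < 0) or np.any(np.diff(self.areas_nm2) < -1e-9)
        ):
            raise ValueError("areas must be non-negative and non-decreasing")

    def __len__(self) -> int:
        return len(self.times_s)

    def growth_window(self, lo_frac: float = 0.05, hi_frac: float = 0.95) -> "GrowthCurve":
        """Restrict to the growth phase (5%–95% of final area by default)."""
        if len(self) == 0:
            return self
        final = self.areas_nm2[-1]
        mask = (self.areas_nm2 >= lo_frac * final) & (self.areas_nm2 <= hi_frac * final)
        if mask.sum() < 3:
            return self
        return GrowthCurve(self.times_s[mask], self.areas_nm2[mask])


@dataclass
class RateFit:
    """Fitted growth phases of one aggregate."""

    archetype: str
    rates: dict[str, float]
    rate_se: dict[str, float] = field(default_factory=dict)
    changepoint_s: float | None = None
    termination_s: float | None = None
    residual_sd: float = 0.0
    degenerate: bool = False


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares line fit: (slope, intercept, slope SE, SSE)."""
    n = len(t)
    X = np.column_stack([t, np.ones(n)])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ beta
    sse = float(np.sum((y - pred) ** 2))
    dof = max(n - 2, 1)
    var_t = float(np.sum((t - t.mean()) ** 2))
    se = float(np.sqrt(sse / dof / var_t)) if var_t > 0 else np.inf
    return float(beta[0]), float(beta[1]), se, sse


def fit_single_rate(
    curve: GrowthCurve,
    window: tuple[float, float] | None = None,
    archetype: str = "isotropic",
    rate_name: str = "rx",
) -> RateFit:
    """Single-phase areal growth rate via OLS over the growth phase.

    ``window`` optionally restricts the fit to ``[t_lo, t_hi]`` seconds;
    by default the 5%–95% growth phase is used. The slope is clipped at
    zero (rates are physical). For small aggregates pass
    ``archetype="small", rate_name="r"`` (and a window ending at the
    termination time).
    """
    if window is not None:
        mask = (curve.times_s >= window[0]) & (curve.times_s <= window[1])
        sub = GrowthCurve(curve.times_s[mask], curve.areas_nm2[mask])
    else:
        sub = curve.growth_window()
    if len(sub) < 3:
        raise FitError("need at least 3 points to fit a rate")
    slope, _, se, sse = _ols_line(sub.times_s, sub.areas_nm2)
    return RateFit(
        archetype=archetype,
        rates={rate_name: max(slope, 0.0)},
        rate_se={rate_name: se},
        residual_sd=float(np.sqrt(sse / max(len(sub) - 2, 1))),
    )


def _piecewise_design(t: np.ndarray, tc: float) -> np.ndarray:
    return np.column_stack([np.ones_like(t), t, np.maximum(t - tc, 0.0)])


def fit_two_phase(
    curve: GrowthCurve,
    min_improvement: float = 0.25,
    use_growth_window: bool = True,
) -> RateFit:
    """Continuous two-segment piecewise-linear fit with one changepoint.

    The changepoint is chosen by exhaustive search over interior
    observed time points (at least two points on each side), minimizing
    total SSE. If the two-phase fit does not improve the single-line SSE
    by at least ``min_improvement`` (fractionally), the fit is flagged
    degenerate and both rates equal the single-phase slope.
    """
    sub = curve.growth_window() if use_growth_window else curve
    if len(sub) < 6:
        raise FitError("need at least 6 points for a two-phase fit")
    t, y = sub.times_s, sub.areas_nm2

    slope1, _, se1, sse_line = _ols_line(t, y)

    best = None
    for i in range(2, len(t) - 2):
        tc = t[i]
        X = _piecewise_design(t, tc)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ beta) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, tc, beta, X)
    sse2, tc, beta, X = best

    scale = float(np.sum((y - y.mean()) ** 2))
    degenerate = sse_line <= 1e-9 * max(scale, 1.0) or (
        sse_line > 0 and (sse_line - sse2) / sse_line < min_improvement
    )
    if degenerate:
        r = max(slope1, 0.0)
        return RateFit(
            archetype="anisotropic",
            rates={"r1": r, "r2": r},
            rate_se={"r1": se1, "r2": se1},
            changepoint_s=None,
            residual_sd=float(np.sqrt(sse_line / max(len(t) - 2, 1))),
            degenerate=True,
        )

    r1 = float(beta[1])
    r2 = float(beta[1] + beta[2])
    dof = max(len(t) - 3, 1)
    sigma2 = sse2 / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se_r1 = float(np.sqrt(cov[1, 1]))
    se_r2 = float(np.sqrt(cov[1, 1] + cov[2, 2] + 2 * cov[1, 2]))
    return RateFit(
        archetype="anisotropic",
        rates={"r1": max(r1, 0.0), "r2": max(r2, 0.0)},
        rate_se={"r1": se_r1, "r2": se_r2},
        changepoint_s=float(tc),
        residual_sd=float(np.sqrt(sigma2)),
        degenerate=False,
    )


def detect_termination(
    curve: GrowthCurve, plateau_window_s: float, slope_tol: float = 0.1
) -> float | None:
    """Earliest time after which growth stays below a slope threshold.

    Rolling-window slopes are computed over ``plateau_window_s``; the
    detected termination is the earliest time from which every later
    rolling slope is below ``slope_tol`` times the maximum rolling
    slope. Returns None for a curve that keeps growing; a completely
    flat curve terminates at its start.
    """
    t, y = curve.times_s, curve.areas_nm2
    if len(t) < 3:
        raise FitError("need at least 3 points")
    if plateau_window_s >= t[-1] - t[0]:
        raise ValueError("plateau_window_s must be smaller than the curve span")
    starts = []
    slopes = []
    for i in range(len(t)):
        mask = (t >= t[i]) & (t <= t[i] + plateau_window_s)
        if mask.sum() < 2:
            break
        ts, ys = t[mask], y[mask]
        slopes.append(np.polyfit(ts, ys, 1)[0])
        starts.append(t[i])
    slopes = np.asarray(slopes)
    max_slope = slopes.max() if len(slopes) else 0.0
    flat_tol = 1e-12 * (np.abs(y).max() + 1.0) / (t[-1] - t[0])
    if max_slope <= flat_tol:
        return float(t[0])
    below = slopes < slope_tol * max_slope
    # earliest index from which `below` holds for all later windows
    ok_from = None
    for i in range(len(below) - 1, -1, -1):
        if below[i]:
            ok_from = i
        else:
            break
    if ok_from is None:
        return None
    return float(starts[ok_from])


def welch_t_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Welch t-test (Satterthwaite degrees of freedom).

    Returns ``(t, p)``. If both samples have zero variance and equal
    means, ``(0.0, 1.0)`` is returned.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ConditionSummary:
    """Per-condition, per-archetype rate statistics."""

    condition: str
    table: pd.DataFrame  # archetype, rate_name, n, mean, se, single_fit_flag

    def n_total(self) -> int:
        per = self.table.drop_duplicates("archetype")[["archetype", "n"]]
        return int(per["n"].sum())


ARCHETYPE_RATES = {
    "anisotropic": ("r1", "r2"),
    "isotropic": ("rx",),
    "small": ("r",),
}


def summarize_condition(fits: list[RateFit], condition: str) -> ConditionSummary:
    """Mean ± SE of each rate per archetype (SE = SD/sqrt(n)).

    Archetypes with no fits appear with n = 0; a single fit is reported
    with SE 0 and ``single_fit=True``.
    """
    rows = []
    for archetype, rate_names in ARCHETYPE_RATES.items():
        members = [f for f in fits if f.archetype == archetype]
        for rate_name in rate_names:
            vals = np.array(
                [f.rates[rate_name] for f in members if rate_name in f.rates]
            )
            n = len(vals)
            mean = float(vals.mean()) if n else np.nan
            if n >= 2:
                se = float(vals.std(ddof=1) / np.sqrt(n))
            else:
                se = 0.0
            rows.append(
                {
                    "archetype": archetype,
                    "rate_name": rate_name,
                    "n": n,
                    "mean_rate_nm2_per_s": mean,
                    "se_nm2_per_s": se,
                    "single_fit": n == 1,
                }
            )
    return ConditionSummary(condition=condition, table=pd.DataFrame(rows))
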