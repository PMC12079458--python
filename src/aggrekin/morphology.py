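"""Time-resolved shape features and archetype classification.

Aggregate area is measured with an occupancy grid: at each time tick the
area is the number of ``grid_nm`` square cells that contain at least one
localization acquired so far, times the cell area. Cumulative occupancy
makes the curve non-decreasing by construction and — unlike a convex
hull — does not overestimate dendritic shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from aggrekin.kinetics import GrowthCurve
from aggrekin.locio import LocalizationTable
from aggrekin.segment import AggregateCluster

NM2_PER_UM2 = 1e6

#: Classification defaults; the area threshold separating small
#: aggregates from spherulites is 10 um².
DEFAULT_CONFIG = dict(
    small_area_threshold_um2=10.0,
    axis_ratio_cut=1.8,
    early_fraction=0.3,
    grid_nm=100.0,
    cadence_s=300.0,
)


@dataclass
class MorphologyFingerprint:
    """Per-time-point area and anisotropy of one aggregate.

    ``axis_ratio`` is the square root of the ratio of the larger to the
    smaller eigenvalue of the positional covariance of all localizations
    up to each time point (>= 1 by construction).
    """

    times_s: np.ndarray
    area_nm2: np.ndarray
    axis_ratio: np.ndarray

    @property
    def final_area_um2(self) -> float:
        return float(self.area_nm2[-1]) / NM2_PER_UM2 if len(self.area_nm2) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "area_nm2": self.area_nm2,
                "axis_ratio": self.axis_ratio,
            }
        )


@dataclass
class AggregateClassification:
    label: str  # anisotropic | isotropic | small
    final_area_um2: float
    early_axis_ratio: float
    terminated: bool = False


def _occupancy_counts(
    xy: np.ndarray, times: np.ndarray, ticks: np.ndarray, grid_nm: float
) -> np.ndarray:
    """Number of distinct occupied grid cells at each tick (cumulative)."""
    cells = np.floor(xy / grid_nm).astype(np.int64)
    # first time each distinct cell is hit
    order = np.argsort(times, kind="stable")
    cells = cells[order]
    t_sorted = times[order]
    _, first_idx = np.unique(cells, axis=0, return_index=True)
    first_times = np.sort(t_sorted[first_idx])
    return np.searchsorted(first_times, ticks, side="right")


def compute_area_curve(
    cluster: AggregateCluster,
    table: LocalizationTable,
    grid_nm: float | None = None,
    cadence_s: float | None = None,
) -> GrowthCurve:
    """Occupancy-grid area versus time for one aggregate.

    At each cadence tick, area = (number of occupied cells) * grid_nm².
    """
    grid_nm = DEFAULT_CONFIG["grid_nm"] if grid_nm is None else grid_nm
    cadence_s = DEFAULT_CONFIG["cadence_s"] if cadence_s is None else cadence_s
    if grid_nm <= 0:
        raise ValueError("grid_nm must be > 0")
    if cadence_s < table.frame_interval_s:
        raise ValueError("cadence_s must be at least one frame interval")
    rows = cluster.member_rows
    if len(rows) == 0:
        return GrowthCurve(np.array([]), np.array([]))
    xy = table.xy[rows]
    times = table.times_s[rows]
    t_end = times.max()
    ticks = np.arange(cadence_s, t_end + cadence_s + 1e-9, cadence_s)
    counts = _occupancy_counts(xy, times, ticks, grid_nm)
    return GrowthCurve(ticks, counts * grid_nm**2)


def compute_fingerprint(
    cluster: AggregateCluster,
    table: LocalizationTable,
    grid_nm: float | None = None,
    cadence_s: float | None = None,
) -> MorphologyFingerprint:
    """Area curve plus cumulative-covariance axis ratio per tick."""
    curve = compute_area_curve(cluster, table, grid_nm, cadence_s)
    rows = cluster.member_rows
    xy = table.xy[rows]
    times = table.times_s[rows]
    order = np.argsort(times, kind="stable")
    xy, times = xy[order], times[order]
    ratios = np.ones(len(curve.times_s))
    for i, tick in enumerate(curve.times_s):
        pts = xy[times <= tick]
        if len(pts) < 3:
            continue
        cov = np.cov(pts.T)
        ev = np.linalg.eigvalsh(cov)
        if ev[0] <= 0:
            ratios[i] = np.inf if ev[1] > 0 else 1.0
        else:
            ratios[i] = np.sqrt(ev[1] / ev[0])
    return MorphologyFingerprint(curve.times_s, curve.areas_nm2, ratios)


def growth_phase_mask(
    areas: np.ndarray, lo_frac: float = 0.05, hi_frac: float = 0.95
) -> np.ndarray:
    """Ticks where the area is between ``lo_frac`` and ``hi_frac`` of final.

    Trims nucleus and plateau artifacts before slope or shape analysis.
    """
    if len(areas) == 0:
        return np.zeros(0, bool)
    final = areas[-1]
    if final <= 0:
        return np.ones(len(areas), bool)
    return (areas >= lo_frac * final) & (areas <= hi_frac * final)


def classify(
    fingerprint: MorphologyFingerprint,
    small_area_threshold_um2: float | None = None,
    axis_ratio_cut: float | None = None,
    early_fraction: float | None = None,
    terminated: bool = False,
) -> AggregateClassification:
    """Classify an aggregate as anisotropic, isotropic, or small.

    Small iff the final occupied area is below the area threshold.
    Otherwise anisotropic iff the median axis ratio over the first
    ``early_fraction`` of the growth phase reaches ``axis_ratio_cut``.
    """
    if len(fingerprint.times_s) == 0:
        raise ValueError("empty fingerprint")
    cfg = DEFAULT_CONFIG
    thr = cfg["small_area_threshold_um2"] if small_area_threshold_um2 is None else small_area_threshold_um2
    cut = cfg["axis_ratio_cut"] if axis_ratio_cut is None else axis_ratio_cut
    frac = cfg["early_fraction"] if early_fraction is None else early_fraction

    mask = growth_phase_mask(fingerprint.area_nm2)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        idx = np.arange(len(fingerprint.times_s))
    n_early = max(1, int(np.ceil(frac * len(idx))))
    early_ratio = float(np.median(fingerprint.axis_ratio[idx[:n_early]]))

    final_area = fingerprint.final_area_um2
    if final_area < thr:
        label = "small"
    elif early_ratio >= cut:
        label = "anisotropic"
    else:
        label = "isotropic"
    return AggregateClassification(
        label=label,
        final_area_um2=final_area,
        early_axis_ratio=early_ratio,
        terminated=terminated,
    )
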