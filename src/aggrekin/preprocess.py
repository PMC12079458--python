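"""Quality filtering and drift correction.

Drift is estimated by redundant cross-correlation of time-binned
reconstruction images against the first time bin, with parabolic
sub-pixel refinement of the correlation peak, then removed by
interpolating the per-bin displacements over time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from aggrekin.locio import LocalizationTable, render_reconstruction

logger = logging.getLogger(__name__)


class DriftEstimationError(RuntimeError):
    pass


@dataclass
class DriftModel:
    """Piecewise-linear drift: displacement (dx, dy) in nm at bin times.

    Displacement at t = 0 is (0, 0) by construction (the first time bin
    is the reference). Between bin times the displacement is linearly
    interpolated; beyond the last bin it is linearly extrapolated from
    the final segment.
    """

    times_s: np.ndarray
    dx_nm: np.ndarray
    dy_nm: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, float)
        self.dx_nm = np.asarray(self.dx_nm, float)
        self.dy_nm = np.asarray(self.dy_nm, float)

    def displacement_at(self, t: np.ndarray) -> np.ndarray:
        """(n, 2) displacement at times ``t`` (seconds)."""
        t = np.atleast_1d(np.asarray(t, float))
        out = np.column_stack(
            [np.interp(t, self.times_s, self.dx_nm), np.interp(t, self.times_s, self.dy_nm)]
        )
        if len(self.times_s) >= 2:  # extrapolate past the last bin
            t1, t0 = self.times_s[-1], self.times_s[-2]
            slope = np.array(
                [
                    (self.dx_nm[-1] - self.dx_nm[-2]) / (t1 - t0),
                    (self.dy_nm[-1] - self.dy_nm[-2]) / (t1 - t0),
                ]
            )
            late = t > t1
            out[late] = np.array([self.dx_nm[-1], self.dy_nm[-1]]) + np.outer(
                t[late] - t1, slope
            )
        return out

    def inverted(self) -> "DriftModel":
        return DriftModel(self.times_s.copy(), -self.dx_nm, -self.dy_nm)


def otsu_intensity_threshold(table: LocalizationTable) -> float:
    """Default intensity cut: Otsu split of the log-intensity histogram."""
    inten = table.intensity
    inten = inten[inten > 0]
    if len(inten) < 2 or np.ptp(np.log(inten)) == 0:
        return 0.0
    return float(np.exp(threshold_otsu(np.log(inten), nbins=256)))


def filter_intensity(
    table: LocalizationTable, threshold: float | None = None
) -> LocalizationTable:
    """Remove localizations with intensity below ``threshold``.

    ``threshold=None`` applies the Otsu default. The number of removed
    rows is logged.
    """
    if threshold is None:
        threshold = otsu_intensity_threshold(table)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = table.intensity >= threshold
    logger.info(
        "intensity filter (threshold %.1f): removed %d of %d localizations",
        threshold,
        int((~keep).sum()),
        len(table),
    )
    return table.replace_data(table.data.loc[keep])


def _xcorr_shift(
    ref: np.ndarray, img: np.ndarray, plateau_frac: float = 0.75
) -> tuple[float, float]:
    """Shift (dy, dx) in pixels maximizing cross-correlation of img vs ref.

    FFT cross-correlation, refined to sub-pixel precision by taking the
    correlation-weighted centroid of the connected region around the
    peak that exceeds ``plateau_frac`` of the peak value. For a sharp
    peak this reduces to parabolic-style interpolation; for the broad
    plateau produced by a structure that grew between the two
    reconstructions it returns the plateau center, which is the
    translation component.
    """
    from scipy import ndimage

    f_ref = np.fft.rfft2(ref)
    f_img = np.fft.rfft2(img)
    corr = np.fft.irfft2(f_ref * np.conj(f_img), s=ref.shape)
    corr = np.fft.fftshift(corr)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    center = np.array(corr.shape) // 2

    floor = float(np.median(corr))
    level = floor + plateau_frac * (float(corr[peak]) - floor)
    mask = corr >= level
    labeled, _ = ndimage.label(mask)
    region = labeled == labeled[peak]
    weights = np.where(region, corr - level, 0.0)
    total = weights.sum()
    if total <= 0:
        dy, dx = float(peak[0]), float(peak[1])
    else:
        ys, xs = np.mgrid[0 : corr.shape[0], 0 : corr.shape[1]]
        dy = float((weights * ys).sum() / total)
        dx = float((weights * xs).sum() / total)
    return -(dy - center[0]), -(dx - center[1])


def estimate_drift(
    table: LocalizationTable,
    bin_duration_s: float,
    pixel_nm: float = 50.0,
    min_localizations_per_bin: int = 50,
) -> DriftModel:
    """Estimate stage drift from time-binned reconstructions.

    The table's time span is split into bins of ``bin_duration_s``; each
    bin is rendered at ``pixel_nm`` resolution and cross-correlated with
    the first bin. Displacements are assigned to bin centers; t = 0 is
    anchored at zero displacement.

    Raises
    ------
    DriftEstimationError
        If fewer than two bins have at least
        ``min_localizations_per_bin`` localizations.
    """
    if len(table) == 0:
        raise DriftEstimationError("empty table")
    times = table.times_s
    t_end = times.max() + table.frame_interval_s
    n_bins = max(2, int(np.ceil(t_end / bin_duration_s)))
    edges = np.arange(n_bins + 1) * bin_duration_s

    counts = np.histogram(times, bins=edges)[0]
    usable = counts >= min_localizations_per_bin
    if usable.sum() < 2 or not usable[0]:
        raise DriftEstimationError(
            "not enough localizations per time bin; increase bin_duration_s"
        )

    xy = table.xy
    pad = 5 * pixel_nm
    bounds = (
        xy[:, 0].min() - pad,
        xy[:, 0].max() + pad,
        xy[:, 1].min() - pad,
        xy[:, 1].max() + pad,
    )

    def bin_image(lo: float, hi: float) -> np.ndarray:
        mask = (times >= lo) & (times < hi)
        sub = table.replace_data(table.data.loc[mask])
        img = render_reconstruction(sub, pixel_nm, bounds_nm=bounds)
        return np.clip(img, 0, 5)  # tame hot pixels

    ref = bin_image(edges[0], edges[1])
    bin_times = [0.0, (edges[0] + edges[1]) / 2.0]
    dxs, dys = [0.0, 0.0], [0.0, 0.0]
    for b in range(1, n_bins):
        if not usable[b]:
            continue
        img = bin_image(edges[b], edges[b + 1])
        dy_px, dx_px = _xcorr_shift(ref, img)
        bin_times.append((edges[b] + edges[b + 1]) / 2.0)
        dxs.append(dx_px * pixel_nm)
        dys.append(dy_px * pixel_nm)
    return DriftModel(np.array(bin_times), np.array(dxs), np.array(dys))


def apply_drift(table: LocalizationTable, model: DriftModel) -> LocalizationTable:
    """Shift localizations by minus the model displacement at their time."""
    disp = model.displacement_at(table.times_s)
    data = table.data.copy()
    data["x_nm"] = data["x_nm"].to_numpy() - disp[:, 0]
    data["y_nm"] = data["y_nm"].to_numpy() - disp[:, 1]
    return table.replace_data(data)
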