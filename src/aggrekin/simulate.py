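"""Ground-truth-labeled synthetic acquisitions.

Emulates sparse-binding super-resolution acquisitions of growing
aggregates: per frame, new binding events are drawn uniformly on the
current occupied footprint with expected count proportional to
``binding_rate_per_area * area``, jittered by localization noise.
Three growth archetypes are supported:

``anisotropic``
    An elongating capsule (dendritic phase, areal rate ``r1``) up to
    ``t_switch``, then isotropic dilation of that capsule (branching
    phase, areal rate ``r2``).
``isotropic``
    A disc whose area grows linearly at rate ``rx``.
``small``
    A disc growing at ``r_small`` until ``t_term``, after which growth
    stops and binding drops to a small residual (default 2% of the
    pre-termination event rate).

Footprint area is piecewise-linear in time by construction, which is the
property the downstream rate-fitting stage estimates.

Bulk turbidity curves are simulated as logistic sigmoids parameterised
directly by their baseline-tangent lag time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point
from shapely.geometry.base import BaseGeometry

from aggrekin.locio import LocalizationTable

Archetype = Literal["anisotropic", "isotropic", "small"]

#: Residual binding after small-aggregate termination, as a fraction of
#: the event rate at the moment of termination.
RESIDUAL_BINDING_FRACTION = 0.02


class InvalidConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class GrowthModel:
    """Growth law of a single aggregate.

    All rates are areal growth rates in nm²/s. ``aspect_ratio_phase1``
    is the target major/minor axis ratio reached at the end of the
    elongated phase of anisotropic growth.
    """

    archetype: Archetype
    r1: float = 0.0
    r2: float = 0.0
    rx: float = 0.0
    r_small: float = 0.0
    t_switch: float = 0.0
    t_term: float = 0.0
    nucleus_radius: float = 400.0
    aspect_ratio_phase1: float = 4.0

    def __post_init__(self) -> None:
        if self.archetype not in ("anisotropic", "isotropic", "small"):
            raise InvalidConfigError(f"unknown archetype: {self.archetype!r}")
        for name in ("r1", "r2", "rx", "r_small"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.nucleus_radius <= 0:
            raise InvalidConfigError("nucleus_radius must be > 0")
        if self.archetype == "anisotropic" and self.t_switch <= 0:
            raise InvalidConfigError("anisotropic growth requires t_switch > 0")
        if self.archetype == "small" and self.t_term <= 0:
            raise InvalidConfigError("small-aggregate growth requires t_term > 0")
        if self.aspect_ratio_phase1 < 1:
            raise InvalidConfigError("aspect_ratio_phase1 must be >= 1")

    @property
    def nucleus_area(self) -> float:
        return float(np.pi * self.nucleus_radius**2)

    def true_area(self, t: float | np.ndarray) -> np.ndarray:
        """Ground-truth footprint area (nm²) at time ``t`` seconds."""
        t = np.asarray(t, dtype=float)
        a0 = self.nucleus_area
        if self.archetype == "isotropic":
            area = a0 + self.rx * t
        elif self.archetype == "anisotropic":
            area = a0 + np.where(
                t <= self.t_switch,
                self.r1 * t,
                self.r1 * self.t_switch + self.r2 * (t - self.t_switch),
            )
        else:  # small
            area = a0 + self.r_small * np.minimum(t, self.t_term)
        return area

    def footprint(self, t: float) -> BaseGeometry:
        """Ground-truth occupied region at time ``t``, centered at the origin."""
        area = float(self.true_area(t))
        if self.archetype == "isotropic" or self.archetype == "small":
            return Point(0.0, 0.0).buffer(np.sqrt(area / np.pi), quad_segs=64)
        # anisotropic: capsule elongating to aspect_ratio_phase1 at
        # t_switch, then uniform dilation of the t_switch capsule.
        if t <= self.t_switch:
            aspect = 1.0 + (self.aspect_ratio_phase1 - 1.0) * (
                t / self.t_switch if self.t_switch > 0 else 1.0
            )
            return _capsule(area, aspect)
        base = _capsule(float(self.true_area(self.t_switch)), self.aspect_ratio_phase1)
        # exact for a convex base: area(d) = A + P*d + pi*d^2
        extra = area - base.area
        if extra <= 0:
            return base
        p = base.length
        d = (-p + np.sqrt(p**2 + 4 * np.pi * extra)) / (2 * np.pi)
        return base.buffer(d, quad_segs=32)


def _capsule(area: float, aspect: float) -> BaseGeometry:
    """Capsule (stadium) of given area and length/width ratio ``aspect``.

    A capsule of width w and end-to-end length L = aspect*w has area
    w^2*(aspect - 1) + pi*(w/2)^2.
    """
    if aspect <= 1.0 + 1e-9:
        return Point(0.0, 0.0).buffer(np.sqrt(area / np.pi), quad_segs=64)
    w = np.sqrt(area / ((aspect - 1.0) + np.pi / 4.0))
    half_core = (aspect * w - w) / 2.0
    return LineString([(-half_core, 0.0), (half_core, 0.0)]).buffer(
        w / 2.0, quad_segs=32
    )


@dataclass(frozen=True)
class ImagingModel:
    """Acquisition model: timing, noise and event densities.

    ``binding_rate_per_area`` is the expected number of new
    localizations per nm² of occupied footprint per frame.
    ``false_positive_rate`` is the expected number of spurious
    localizations per frame over the whole field of view; their
    intensity is drawn at half the signal intensity.
    """

    frame_interval_s: float = 30.0
    n_frames: int = 240
    localization_sigma_nm: float = 20.0
    binding_rate_per_area: float = 2e-6
    false_positive_rate: float = 0.5
    drift_velocity_nm_per_frame: tuple[float, float] = (0.0, 0.0)
    fov_size_nm: tuple[float, float] = (40_960.0, 40_960.0)
    seed: int = 0
    signal_intensity: float = 1000.0
    intensity_sigma: float = 60.0
    drift_mode: Literal["linear", "sinusoidal"] = "linear"

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise InvalidConfigError("frame_interval_s must be > 0")
        if self.n_frames <= 0:
            raise InvalidConfigError("n_frames must be a positive integer")
        if self.binding_rate_per_area < 0 or self.false_positive_rate < 0:
            raise InvalidConfigError("rates must be >= 0")
        if self.localization_sigma_nm < 0:
            raise InvalidConfigError("localization_sigma_nm must be >= 0")

    def drift_at_frame(self, frames: np.ndarray) -> np.ndarray:
        """Cumulative (n, 2) drift displacement in nm for 1-based frames."""
        f = np.asarray(frames, dtype=float) - 1.0
        v = np.asarray(self.drift_velocity_nm_per_frame, dtype=float)
        if self.drift_mode == "linear":
            return f[:, None] * v[None, :]
        # sinusoidal stress-test drift with one period over the acquisition
        phase = 2 * np.pi * f / max(self.n_frames, 1)
        amp = v * self.n_frames / (2 * np.pi)
        return np.sin(phase)[:, None] * amp[None, :]


@dataclass
class GroundTruth:
    """Per-localization and per-aggregate ground truth for one simulation.

    ``aggregate_ids`` aligns with the rows of the returned table;
    id 0 marks noise (false positives).
    """

    aggregate_ids: np.ndarray
    models: dict[int, GrowthModel] = field(default_factory=dict)
    origins: dict[int, tuple[float, float]] = field(default_factory=dict)
    area_tables: dict[int, pd.DataFrame] = field(default_factory=dict)
    drift_nm: np.ndarray | None = None

    def n_events(self, aggregate_id: int) -> int:
        return int(np.sum(self.aggregate_ids == aggregate_id))


def _sample_in_geometry(
    geom: BaseGeometry, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform samples inside a shapely geometry by rejection sampling."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = geom.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(64, int((n - got) * 2.2))
        pts = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        keep = shapely.contains_xy(geom, pts[:, 0], pts[:, 1])
        take = min(n - got, int(keep.sum()))
        out[got : got + take] = pts[keep][:take]
        got += take
    return out


def _simulate_aggregate_events(
    model: GrowthModel,
    imaging: ImagingModel,
    origin: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw (undrifted) binding events plus the true area table."""
    dt = imaging.frame_interval_s
    frames = np.arange(1, imaging.n_frames + 1)
    times = (frames - 1) * dt
    areas = model.true_area(times)

    rate = imaging.binding_rate_per_area * areas  # events per frame
    if model.archetype == "small":
        terminated = times > model.t_term
        rate_at_term = imaging.binding_rate_per_area * float(
            model.true_area(model.t_term)
        )
        rate = np.where(terminated, RESIDUAL_BINDING_FRACTION * rate_at_term, rate)
    counts = rng.poisson(rate)

    rows = []
    for f, t, c in zip(frames, times, counts):
        if c == 0:
            continue
        pts = _sample_in_geometry(model.footprint(float(t)), int(c), rng)
        rows.append(
            pd.DataFrame(
                {
                    "frame": np.full(c, f, dtype=int),
                    "x_nm": pts[:, 0] + origin[0],
                    "y_nm": pts[:, 1] + origin[1],
                }
            )
        )
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame({"frame": np.array([], int), "x_nm": [], "y_nm": []})
    if imaging.localization_sigma_nm > 0 and len(df):
        df[["x_nm", "y_nm"]] += rng.normal(
            0.0, imaging.localization_sigma_nm, size=(len(df), 2)
        )
    df["intensity"] = np.clip(
        rng.normal(imaging.signal_intensity, imaging.intensity_sigma, size=len(df)),
        1.0,
        None,
    )
    area_table = pd.DataFrame({"time_s": times, "area_nm2": areas})
    return df, area_table


def simulate_aggregate(
    model: GrowthModel,
    imaging: ImagingModel,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[LocalizationTable, GroundTruth]:
    """Simulate the acquisition of a single growing aggregate.

    Returns the localization table (drift applied) and the ground truth
    (all rows belong to aggregate id 1; drift recorded per frame).
    """
    import dataclasses

    return simulate_field_of_view(
        [(model, origin)], dataclasses.replace(imaging, false_positive_rate=0.0)
    )


def simulate_field_of_view(
    mix: Sequence[tuple[GrowthModel, tuple[float, float]]],
    imaging: ImagingModel,
) -> tuple[LocalizationTable, GroundTruth]:
    """Simulate a field of view containing several aggregates.

    Each ``(model, origin)`` pair becomes aggregate id 1, 2, ... in
    order; uniform false positives get id 0. Stage drift is applied
    cumulatively to every localization; ground-truth ids refer to the
    pre-drift geometry. Overlapping origins are allowed (touching
    aggregates are a supported test case).

    The output is fully determined by ``mix`` and ``imaging`` (including
    ``imaging.seed``).
    """
    w, h = imaging.fov_size_nm
    for _, (ox, oy) in mix:
        if not (0 <= ox <= w and 0 <= oy <= h):
            raise InvalidConfigError("aggregate origin outside the field of view")

    root = np.random.SeedSequence(imaging.seed)
    agg_seeds = root.spawn(len(mix) + 1)

    parts: list[pd.DataFrame] = []
    ids: list[np.ndarray] = []
    truth = GroundTruth(aggregate_ids=np.array([], int))
    for k, (model, origin) in enumerate(mix, start=1):
        rng = np.random.default_rng(agg_seeds[k - 1])
        df, area_table = _simulate_aggregate_events(model, imaging, origin, rng)
        parts.append(df)
        ids.append(np.full(len(df), k, dtype=int))
        truth.models[k] = model
        truth.origins[k] = tuple(origin)
        truth.area_tables[k] = area_table

    # false positives, uniform over the FOV, at half the signal intensity
    fp_rng = np.random.default_rng(agg_seeds[-1])
    fp_counts = fp_rng.poisson(imaging.false_positive_rate, size=imaging.n_frames)
    n_fp = int(fp_counts.sum())
    if n_fp:
        fp_frames = np.repeat(np.arange(1, imaging.n_frames + 1), fp_counts)
        fp = pd.DataFrame(
            {
                "frame": fp_frames,
                "x_nm": fp_rng.uniform(0, w, n_fp),
                "y_nm": fp_rng.uniform(0, h, n_fp),
                "intensity": np.clip(
                    fp_rng.normal(
                        imaging.signal_intensity / 2.0,
                        imaging.intensity_sigma,
                        size=n_fp,
                    ),
                    1.0,
                    None,
                ),
            }
        )
        parts.append(fp)
        ids.append(np.zeros(n_fp, dtype=int))

    if parts:
        df = pd.concat(parts, ignore_index=True)
        agg_ids = np.concatenate(ids)
    else:
        df = pd.DataFrame(
            {"frame": np.array([], int), "x_nm": [], "y_nm": [], "intensity": []}
        )
        agg_ids = np.array([], int)

    order = np.argsort(df["frame"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    agg_ids = agg_ids[order]

    drift = imaging.drift_at_frame(df["frame"].to_numpy())
    df[["x_nm", "y_nm"]] += drift

    truth.aggregate_ids = agg_ids
    truth.drift_nm = imaging.drift_at_frame(np.arange(1, imaging.n_frames + 1))
    table = LocalizationTable(
        df, frame_interval_s=imaging.frame_interval_s, fov_nm=imaging.fov_size_nm
    )
    return table, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Sidecar CSV mapping localization row id to ground-truth aggregate id."""
    pd.DataFrame(
        {"row": np.arange(len(truth.aggregate_ids)), "aggregate_id": truth.aggregate_ids}
    ).to_csv(path, index=False)


def benchmark_field_of_view(
    seed: int,
    n_frames: int = 240,
    binding_rate_per_area: float = 3e-6,
    drift_velocity_nm_per_frame: tuple[float, float] = (1.0, -0.5),
) -> tuple[LocalizationTable, GroundTruth]:
    """Standard benchmark acquisition for segmentation scoring.

    One field of view containing all three growth archetypes plus a
    touching pair: an anisotropic spherulite, an isotropic spherulite, a
    small aggregate with terminated growth, and two isotropic aggregates
    nucleating 3 um apart whose footprints merge late. False positives
    and linear stage drift are included.
    """
    duration = n_frames * 30.0
    mix = [
        (
            GrowthModel(
                "anisotropic", r1=1500.0, r2=6000.0, t_switch=0.35 * duration
            ),
            (9_000.0, 9_000.0),
        ),
        (GrowthModel("isotropic", rx=4000.0), (30_000.0, 9_000.0)),
        (GrowthModel("small", r_small=900.0, t_term=0.5 * duration), (9_000.0, 30_000.0)),
        (GrowthModel("isotropic", rx=3000.0), (27_000.0, 29_000.0)),
        (GrowthModel("isotropic", rx=3000.0), (30_000.0, 29_000.0)),
    ]
    imaging = ImagingModel(
        seed=seed,
        n_frames=n_frames,
        binding_rate_per_area=binding_rate_per_area,
        false_positive_rate=2.0,
        drift_velocity_nm_per_frame=drift_velocity_nm_per_frame,
    )
    return simulate_field_of_view(mix, imaging)


# ---------------------------------------------------------------------------
# turbidity
# ---------------------------------------------------------------------------


def turbidity_sigmoid(
    t: np.ndarray, lag_min: float, growth_rate: float, plateau: float
) -> np.ndarray:
    """Noiseless logistic turbidity curve with a given tangent lag.

    The logistic ``plateau / (1 + exp(-k (t - t0)))`` has its steepest
    tangent at ``t0`` with slope ``plateau * k / 4``; that tangent meets
    the zero baseline at ``t0 - 2 / k``. Setting ``t0 = lag_min + 2/k``
    therefore makes the baseline-tangent lag equal ``lag_min`` exactly.
    """
    t = np.asarray(t, dtype=float)
    t0 = lag_min + 2.0 / growth_rate
    return plateau / (1.0 + np.exp(-growth_rate * (t - t0)))


def simulate_turbidity(
    lag_min: float,
    growth_rate: float,
    plateau: float,
    noise_sd: float,
    t_grid: Sequence[float],
    n_replicates: int,
    seed: int = 0,
    condition: str = "condition",
) -> pd.DataFrame:
    """Simulate replicate turbidity kinetics curves.

    Returns a long-format frame with columns ``condition``,
    ``replicate``, ``time_min``, ``absorbance``. Replicate noise is iid
    Gaussian on the absorbance.
    """
    t = np.asarray(t_grid, dtype=float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise InvalidConfigError("t_grid must be strictly increasing")
    if plateau < 0:
        raise InvalidConfigError("plateau must be non-negative")
    if n_replicates < 1:
        raise InvalidConfigError("n_replicates must be >= 1")
    if growth_rate <= 0:
        raise InvalidConfigError("growth_rate must be > 0")

    rng = np.random.default_rng(seed)
    clean = turbidity_sigmoid(t, lag_min, growth_rate, plateau)
    frames = []
    for rep in range(1, n_replicates + 1):
        noisy = clean + rng.normal(0.0, noise_sd, size=len(t)) if noise_sd > 0 else clean
        frames.append(
            pd.DataFrame(
                {
                    "condition": condition,
                    "replicate": rep,
                    "time_min": t,
                    "absorbance": noisy,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
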