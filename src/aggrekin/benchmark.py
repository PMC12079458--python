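"""End-to-end benchmark scoring on synthetic acquisitions.

Runs the full default pipeline — intensity filtering (automatic Otsu
threshold), drift estimation and correction, incremental segmentation —
on a benchmark field of view and scores the per-localization assignment
against the ground truth.
"""

from __future__ import annotations

import numpy as np

from aggrekin.preprocess import (
    DriftEstimationError,
    apply_drift,
    estimate_drift,
    filter_intensity,
    otsu_intensity_threshold,
)
from aggrekin.segment import assignment_accuracy, cluster_incremental
from aggrekin.simulate import benchmark_field_of_view


def benchmark_assignment_accuracy(seed: int, n_frames: int = 240) -> float:
    """Per-localization assignment accuracy of the default pipeline.

    Simulates one benchmark field of view (three growth archetypes plus
    a touching pair, false positives, linear drift), applies the default
    preprocessing and segmentation, and returns the accuracy against the
    ground-truth sidecar after optimal label matching.
    """
    table, truth = benchmark_field_of_view(seed, n_frames=n_frames)
    threshold = otsu_intensity_threshold(table)
    keep = table.intensity >= threshold
    filtered = filter_intensity(table, threshold)
    try:
        drift = estimate_drift(filtered, bin_duration_s=1800.0, pixel_nm=50.0)
        filtered = apply_drift(filtered, drift)
    except DriftEstimationError:
        pass
    _, labels = cluster_incremental(filtered)
    return assignment_accuracy(labels, truth.aggregate_ids[keep])


def mean_benchmark_accuracy(seeds: list[int], n_frames: int = 240) -> float:
    return float(np.mean([benchmark_assignment_accuracy(s, n_frames) for s in seeds]))
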