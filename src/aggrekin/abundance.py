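"""Condition-level aggregate-type abundance statistics.

Per-image counts of spherulites and small aggregates are summed per
condition and the small-aggregate percentage is reported as an integer
(half-away-from-zero rounding).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def percent_small(n_spherulites: int, n_small: int) -> int:
    """Integer percentage of small aggregates among all counted aggregates.

    Rounds half away from zero, e.g. (68, 5) -> 7 and (35, 62) -> 64.
    """
    if n_spherulites < 0 or n_small < 0:
        raise ValueError("counts must be non-negative")
    total = n_spherulites + n_small
    if total == 0:
        raise ValueError("undefined: no aggregates counted")
    return int(math.floor(100.0 * n_small / total + 0.5))


def tabulate(per_image_counts: pd.DataFrame) -> pd.DataFrame:
    """Sum per-image counts into a per-condition count table.

    Input columns: ``condition``, ``image`` (or any replicate id),
    ``n_spherulites``, ``n_small``. Output: one row per condition with
    totals, the integer percentage of small aggregates, and the
    standard error of the per-image counts.
    """
    required = {"condition", "n_spherulites", "n_small"}
    missing = required - set(per_image_counts.columns)
    if missing:
        raise ValueError(f"missing column(s): {', '.join(sorted(missing))}")
    if len(per_image_counts) == 0:
        return pd.DataFrame(
            columns=[
                "condition",
                "n_spherulites",
                "n_small",
                "percent_small",
                "se_spherulites",
                "se_small",
                "n_images",
            ]
        )
    rows = []
    for condition, grp in per_image_counts.groupby("condition", sort=False):
        sph = grp["n_spherulites"].to_numpy(float)
        sml = grp["n_small"].to_numpy(float)
        n_img = len(grp)

        def se(v: np.ndarray) -> float:
            return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) >= 2 else 0.0

        total_sph, total_sml = int(sph.sum()), int(sml.sum())
        rows.append(
            {
                "condition": condition,
                "n_spherulites": total_sph,
                "n_small": total_sml,
                "percent_small": percent_small(total_sph, total_sml)
                if total_sph + total_sml
                else np.nan,
                "se_spherulites": se(sph),
                "se_small": se(sml),
                "n_images": n_img,
            }
        )
    return pd.DataFrame(rows)
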