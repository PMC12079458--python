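"""Incremental spatiotemporal segmentation of growing aggregates.

Localizations are processed in time windows. Within each window a
density clustering (DBSCAN on x, y) is run over the window's points —
augmented with all previously assigned points, which act as seeds — and
each dense group is linked to an existing aggregate, split between
aggregates along their seed pathways, or registered as a new aggregate.
Assignments are never revoked; points that have not yet fallen in a
dense region remain candidates in later windows and end up as noise if
they never do.

With a single window covering the whole acquisition the procedure
reduces exactly to plain DBSCAN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from aggrekin.locio import LocalizationTable

#: Default clustering configuration. ``merge_radius_nm`` bounds the
#: distance between birth centroids below which two aggregates are
#: considered fragments of the same structure and merged.
DEFAULTS = dict(
    window_s=300.0,
    eps_nm=100.0,
    min_pts=5,
    link_radius_nm=500.0,
    merge_radius_nm=1500.0,
)


@dataclass
class AggregateCluster:
    """One segmented aggregate: member rows plus its temporal extent."""

    aggregate_id: int
    member_rows: np.ndarray
    first_time_s: float
    last_time_s: float
    centroid_track: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __len__(self) -> int:
        return len(self.member_rows)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def add(self, x: int) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        lo, hi = min(ra, rb), max(ra, rb)  # keep the older (lower) id
        self.parent[hi] = lo
        return lo


def cluster_incremental(
    table: LocalizationTable,
    window_s: float | None = None,
    eps_nm: float | None = None,
    min_pts: int | None = None,
    link_radius_nm: float | None = None,
    merge_radius_nm: float | None = None,
) -> tuple[list[AggregateCluster], np.ndarray]:
    """Assign each localization to an aggregate or to noise.

    Returns ``(clusters, labels)`` where ``labels`` aligns with the
    table rows: positive aggregate ids, or 0 for noise.

    Per window, DBSCAN runs over the not-yet-assigned localizations seen
    so far plus all assigned points (seeds). Each dense group is then

    * assigned to the single aggregate whose seeds it contains,
    * split along seed pathways (nearest assigned point) when it joins
      several aggregates whose birth centroids are farther apart than
      ``merge_radius_nm`` (genuinely intertwined structures),
    * merged into one aggregate when the joined aggregates were born
      closer than ``merge_radius_nm`` (fragments of one structure), or
    * linked to the aggregate with the nearest member point within
      ``link_radius_nm`` — ties to the lower id — or registered as a
      newborn aggregate.
    """
    window_s = DEFAULTS["window_s"] if window_s is None else window_s
    eps_nm = DEFAULTS["eps_nm"] if eps_nm is None else eps_nm
    min_pts = DEFAULTS["min_pts"] if min_pts is None else min_pts
    link_radius_nm = (
        DEFAULTS["link_radius_nm"] if link_radius_nm is None else link_radius_nm
    )
    merge_radius_nm = (
        DEFAULTS["merge_radius_nm"] if merge_radius_nm is None else merge_radius_nm
    )
    if window_s < table.frame_interval_s:
        raise ValueError("window_s must be at least one frame interval")
    if eps_nm <= 0 or min_pts < 2:
        raise ValueError("eps_nm must be > 0 and min_pts >= 2")

    n = len(table)
    labels = np.zeros(n, dtype=int)
    if n == 0:
        return [], labels

    xy = table.xy
    times = table.times_s
    t_end = times.max()
    n_windows = max(1, int(np.ceil((t_end + table.frame_interval_s) / window_s)))

    next_id = 1
    uf = _UnionFind()
    births: dict[int, np.ndarray] = {}  # root id -> birth centroid
    track: dict[int, list[tuple[float, float, float]]] = {}

    for w in range(n_windows):
        hi = (w + 1) * window_s if w < n_windows - 1 else np.inf
        candidates = np.flatnonzero((labels == 0) & (times < hi))
        if len(candidates) == 0:
            continue
        seeds = np.flatnonzero(labels > 0)
        pool = np.concatenate([candidates, seeds])
        dblab = DBSCAN(eps=eps_nm, min_samples=min_pts).fit(xy[pool]).labels_
        n_cand = len(candidates)

        # groups with seeds first, then seedless by size, so fresh
        # fragments can link to aggregates updated earlier in the window
        groups = []
        for c in np.unique(dblab):
            if c == -1:
                continue
            members = np.flatnonzero(dblab == c)
            new_local = members[members < n_cand]
            if len(new_local) == 0:
                continue
            seed_local = members[members >= n_cand]
            groups.append((c, new_local, seed_local))
        groups.sort(key=lambda g: (len(g[2]) == 0, -len(g[1])))

        for _, new_local, seed_local in groups:
            new_rows = candidates[new_local]
            seed_rows = (
                seeds[seed_local - n_cand] if len(seed_local) else np.array([], int)
            )
            seed_aggs = (
                np.unique([uf.find(a) for a in labels[seed_rows]])
                if len(seed_rows)
                else np.array([], int)
            )

            if len(seed_aggs) > 1:
                # merge aggregates whose origins nearly coincide
                roots = list(seed_aggs)
                merged = True
                while merged and len(roots) > 1:
                    merged = False
                    for i in range(len(roots)):
                        for j in range(i + 1, len(roots)):
                            d = np.linalg.norm(births[roots[i]] - births[roots[j]])
                            if d <= merge_radius_nm:
                                keep = uf.union(roots[i], roots[j])
                                drop = roots[j] if keep == roots[i] else roots[i]
                                births.pop(drop, None)
                                roots = [r for r in roots if r != drop]
                                merged = True
                                break
                        if merged:
                            break
                seed_aggs = np.asarray(roots)
                assigned = labels > 0
                labels[assigned] = np.array(
                    [uf.find(a) for a in labels[assigned]]
                )

            if len(seed_aggs) == 1:
                labels[new_rows] = seed_aggs[0]
            elif len(seed_aggs) > 1:
                # intertwined: follow the pathway of the nearest seed
                roots_of_seeds = labels[seed_rows]
                dists = np.column_stack(
                    [
                        cKDTree(xy[seed_rows[roots_of_seeds == a]]).query(
                            xy[new_rows], k=1
                        )[0]
                        for a in seed_aggs
                    ]
                )
                labels[new_rows] = seed_aggs[np.argmin(dists, axis=1)]
            else:
                # no seeds: link by footprint proximity, else newborn
                tree = cKDTree(xy[new_rows])
                best_id, best_d = None, np.inf
                for agg_id in sorted(births):
                    member = np.flatnonzero(labels == agg_id)
                    if len(member) == 0:
                        continue
                    d = tree.query(xy[member], k=1)[0].min()
                    if d < best_d - 1e-12:
                        best_id, best_d = agg_id, d
                if best_id is not None and best_d <= link_radius_nm:
                    labels[new_rows] = best_id
                else:
                    uf.add(next_id)
                    births[next_id] = xy[new_rows].mean(axis=0)
                    labels[new_rows] = next_id
                    next_id += 1

        # canonicalize labels to current roots
        assigned = labels > 0
        if assigned.any():
            labels[assigned] = np.array([uf.find(a) for a in labels[assigned]])

        t_mid = min((w + 0.5) * window_s, t_end)
        for agg_id in np.unique(labels[assigned]):
            rows = np.flatnonzero(labels == agg_id)
            cx, cy = xy[rows].mean(axis=0)
            track.setdefault(int(agg_id), []).append((t_mid, cx, cy))

    # compact ids to 1..K in birth order
    final_ids = sorted(set(int(uf.find(a)) for a in labels[labels > 0]))
    remap = {old: i + 1 for i, old in enumerate(final_ids)}
    labels = np.array([remap.get(int(a), 0) if a > 0 else 0 for a in labels])

    clusters = []
    for old in final_ids:
        agg_id = remap[old]
        rows = np.flatnonzero(labels == agg_id)
        clusters.append(
            AggregateCluster(
                aggregate_id=agg_id,
                member_rows=rows,
                first_time_s=float(times[rows].min()),
                last_time_s=float(times[rows].max()),
                centroid_track=np.array(track.get(old, np.empty((0, 3)))),
            )
        )
    return clusters, labels


def split_intertwined(
    cluster: AggregateCluster,
    table: LocalizationTable,
    window_s: float | None = None,
    eps_nm: float | None = None,
    min_pts: int | None = None,
    k_windows: int = 3,
    separation_factor: float = 2.0,
) -> list[AggregateCluster]:
    """Split a cluster whose early history shows several density modes.

    The cluster's first ``k_windows`` time windows are re-clustered; if
    they contain two or more dense modes whose per-window centroid
    tracks stay at least ``separation_factor * eps_nm`` apart, the whole
    cluster is partitioned by growing each mode outward: window by
    window, each point joins the group of its nearest already-assigned
    point. Otherwise (or with ``k_windows=0``) the input is returned
    unchanged.

    Mode detection uses twice the assignment ``eps_nm`` by default: the
    early point cloud is sparse, and modes only need to be resolved,
    not delineated.
    """
    if k_windows == 0:
        return [cluster]
    window_s = DEFAULTS["window_s"] if window_s is None else window_s
    eps_nm = 2 * DEFAULTS["eps_nm"] if eps_nm is None else eps_nm
    min_pts = DEFAULTS["min_pts"] if min_pts is None else min_pts

    rows = cluster.member_rows
    xy = table.xy[rows]
    times = table.times_s[rows]
    t0 = cluster.first_time_s
    early = times < t0 + k_windows * window_s
    if early.sum() < 2 * min_pts:
        return [cluster]

    db = DBSCAN(eps=eps_nm, min_samples=min_pts).fit(xy[early])
    mode_labels = db.labels_
    modes = [m for m in np.unique(mode_labels) if m != -1]
    if len(modes) < 2:
        return [cluster]

    # centroid tracks of the early modes must stay distinct
    for w in range(k_windows):
        lo, hi = t0 + w * window_s, t0 + (w + 1) * window_s
        cents = []
        for m in modes:
            sel = (mode_labels == m) & (times[early] >= lo) & (times[early] < hi)
            if sel.sum():
                cents.append(xy[early][sel].mean(axis=0))
        for i in range(len(cents)):
            for j in range(i + 1, len(cents)):
                if np.linalg.norm(cents[i] - cents[j]) < separation_factor * eps_nm:
                    return [cluster]

    # grow each mode outward by nearest-assigned-point pathway
    group = np.full(len(rows), -1, dtype=int)
    early_idx = np.flatnonzero(early)
    for gi, m in enumerate(modes):
        group[early_idx[mode_labels == m]] = gi
    unassigned_early = early_idx[mode_labels == -1]
    if len(unassigned_early):
        tree_pts = [np.flatnonzero(group == gi) for gi in range(len(modes))]
        d = np.column_stack(
            [cKDTree(xy[p]).query(xy[unassigned_early], k=1)[0] for p in tree_pts]
        )
        group[unassigned_early] = np.argmin(d, axis=1)

    order = np.argsort(times, kind="stable")
    remaining = order[group[order] == -1]
    chunk = max(64, len(remaining) // 50 + 1)
    for start in range(0, len(remaining), chunk):
        batch = remaining[start : start + chunk]
        trees = [cKDTree(xy[group == gi]) for gi in range(len(modes))]
        d = np.column_stack([t.query(xy[batch], k=1)[0] for t in trees])
        group[batch] = np.argmin(d, axis=1)

    out = []
    for gi in range(len(modes)):
        sub = rows[group == gi]
        out.append(
            AggregateCluster(
                aggregate_id=cluster.aggregate_id * 100 + gi + 1,
                member_rows=sub,
                first_time_s=float(table.times_s[sub].min()),
                last_time_s=float(table.times_s[sub].max()),
            )
        )
    return out


def count_per_fov(clusters: list[AggregateCluster], min_events: int = 1) -> int:
    """Number of aggregates with at least ``min_events`` member localizations."""
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    return sum(1 for c in clusters if len(c) >= min_events)


def assignment_accuracy(pred_labels: np.ndarray, true_ids: np.ndarray) -> float:
    """Per-localization accuracy after optimal cluster-label matching.

    Predicted labels and ground-truth ids (0 = noise on both sides) are
    matched one-to-one by maximizing the matched count (Hungarian
    algorithm on the contingency table, with noise forced to match
    noise); accuracy is the matched fraction.
    """
    pred_labels = np.asarray(pred_labels)
    true_ids = np.asarray(true_ids)
    if pred_labels.shape != true_ids.shape:
        raise ValueError("label arrays must have the same shape")
    n = len(true_ids)
    if n == 0:
        return 1.0
    pu, pinv = np.unique(pred_labels, return_inverse=True)
    tu, tinv = np.unique(true_ids, return_inverse=True)
    cont = np.zeros((len(pu), len(tu)), dtype=float)
    np.add.at(cont, (pinv, tinv), 1.0)
    # noise is a fixed identity, not a matchable cluster
    bonus = 0.0
    p_noise = np.flatnonzero(pu == 0)
    t_noise = np.flatnonzero(tu == 0)
    if len(p_noise) and len(t_noise):
        bonus = cont[p_noise[0], t_noise[0]]
    keep_p = pu != 0
    keep_t = tu != 0
    cont = cont[keep_p][:, keep_t]
    matched = 0.0
    if cont.size:
        ri, ci = linear_sum_assignment(-cont)
        matched = cont[ri, ci].sum()
    return float((matched + bonus) / n)
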