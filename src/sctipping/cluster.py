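"""Per-time-point hierarchical clustering into subpopulations.

Cells are split by day and clustered with Ward-linkage agglomerative
clustering on the log levels of a marker subset; the number of clusters per
day is either fixed or selected by an elbow rule on the total
within-cluster sum of squares (WSS) curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .data import CLUSTERING_MARKERS, SingleCellTable, ValidationError


@dataclass
class ClusterAssignment:
    """Globally unique per-cell cluster labels, one day per cluster."""

    labels: np.ndarray                     # (m,) int cluster ids
    day_of_cluster: dict[int, int]
    k_per_day: dict[int, int]
    markers_used: tuple[str, ...] | None
    wss_curves: dict[int, list[tuple[int, float]]]

    def cluster_ids(self) -> list[int]:
        return sorted(self.day_of_cluster)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)

    def n_clusters(self) -> int:
        return len(self.day_of_cluster)


def wss_of_labels(data: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared deviations from cluster means."""
    total = 0.0
    for lab in np.unique(labels):
        block = data[labels == lab]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def wss_curve(data: np.ndarray, k_max: int) -> list[tuple[int, float]]:
    """WSS along nested Ward cuts for k = 1..k_max.

    Nested hierarchical cuts make the curve nonincreasing in k.
    """
    data = np.asarray(data, float)
    if k_max < 1:
        raise ValidationError("k_max must be at least 1")
    if k_max > data.shape[0]:
        raise ValidationError("k_max cannot exceed the number of rows")
    if data.shape[0] < 2:
        raise ValidationError("need at least 2 rows")
    link = linkage(data, method="ward")
    curve = []
    for k in range(1, k_max + 1):
        labels = fcluster(link, t=k, criterion="maxclust")
        curve.append((k, wss_of_labels(data, labels)))
    return curve


def elbow_select(curve: Sequence[tuple[int, float]]) -> int:
    """k with the largest discrete second difference of WSS; ties -> smallest.

    The curve must cover consecutive k starting at 1 with at least 3 points.
    """
    ks = [k for k, _ in curve]
    if len(curve) < 3:
        raise ValidationError("elbow selection needs at least 3 curve points")
    if ks != list(range(1, len(ks) + 1)):
        raise ValidationError("curve must cover k = 1..k_max consecutively")
    wss = np.array([w for _, w in curve], dtype=float)
    second = wss[:-2] - 2.0 * wss[1:-1] + wss[2:]  # curvature at k=2..k_max-1
    best = int(np.argmax(second))  # ties: argmax takes the first (smallest k)
    return best + 2


def cluster_by_day(
    table: SingleCellTable,
    markers: Sequence[str] | None = None,
    k_per_day: Mapping[int, int] | int | str = "auto",
    k_max: int = 8,
) -> ClusterAssignment:
    """Ward clustering within each day on the chosen markers.

    ``k_per_day`` is a day -> k map, a single k for every day, or ``"auto"``
    to pick k per day by :func:`elbow_select`.  Cluster ids are globally
    unique, assigned in day order.
    """
    if not table.log_space:
        raise ValidationError("clustering expects a log-space table")
    if markers is None:
        markers = [m for m in CLUSTERING_MARKERS if m in table.panel.names]
        if not markers:
            markers = list(table.panel.names)
    data_all = table.marker_matrix(markers)
    days = table.days_present()
    if len(days) == 0:
        raise ValidationError("table has no cells")

    labels = np.full(table.n_cells, -1, dtype=int)
    day_of_cluster: dict[int, int] = {}
    chosen_k: dict[int, int] = {}
    curves: dict[int, list[tuple[int, float]]] = {}
    next_id = 0
    for day in days:
        idx = np.flatnonzero(table.day == day)
        data = data_all[idx]
        n_day = idx.size
        if isinstance(k_per_day, str):
            if k_per_day != "auto":
                raise ValidationError(f"unknown k mode {k_per_day!r}")
            k_hi = min(k_max, n_day - 1)
            if k_hi < 3:
                raise ValidationError(
                    f"day {day} has too few cells ({n_day}) for elbow selection"
                )
            curve = wss_curve(data, k_hi)
            k = elbow_select(curve)
        else:
            k = k_per_day if isinstance(k_per_day, int) else k_per_day[day]
            if k < 1 or k >= n_day:
                raise ValidationError(
                    f"k={k} invalid for day {day} with {n_day} cells"
                )
            curve = wss_curve(data, min(max(k, 3), n_day))
        link = linkage(data, method="ward")
        day_labels = fcluster(link, t=k, criterion="maxclust")
        chosen_k[day] = int(day_labels.max())
        curves[day] = curve
        for local in range(1, day_labels.max() + 1):
            labels[idx[day_labels == local]] = next_id
            day_of_cluster[next_id] = day
            next_id += 1
    return ClusterAssignment(
        labels=labels,
        day_of_cluster=day_of_cluster,
        k_per_day=chosen_k,
        markers_used=tuple(markers),
        wss_curves=curves,
    )
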