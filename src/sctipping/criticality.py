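"""Tipping-point indices for cell subpopulations.

Near a critical cell-state transition, analyte-analyte correlations rise
while cell-to-cell correlations fall.  Two indices quantify this within a
cluster of cells:

* SNAI (signaling network activity index): the reciprocal of the
  determinant of the analyte-analyte Pearson correlation matrix.  A valid
  correlation matrix has determinant in (0, 1], so SNAI >= 1, diverging as
  the cluster's correlation structure approaches singularity.
* Ic (critical transition index): the mean absolute Pearson correlation
  over analyte pairs divided by the mean absolute correlation over cell
  pairs.

The per-path argmax cluster of either index is the candidate tipping point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cluster import ClusterAssignment
from .data import CLUSTERING_MARKERS, SingleCellTable, ValidationError

DET_EPS = 1e-12


def _check_matrix(X: np.ndarray, min_cells: int, min_analytes: int) -> np.ndarray:
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValidationError("expected a cells x analytes matrix")
    if X.shape[0] < min_cells:
        raise ValidationError(f"need at least {min_cells} cells")
    if X.shape[1] < min_analytes:
        raise ValidationError(f"need at least {min_analytes} analytes")
    return X


def snai(
    values: np.ndarray,
    analyte_names: Sequence[str] | None = None,
    method: str = "pearson",
) -> float:
    """1 / det of the analyte-analyte correlation matrix (>= 1)."""
    value, _, _ = snai_details(values, analyte_names, method=method)
    return value


def snai_details(
    values: np.ndarray,
    analyte_names: Sequence[str] | None = None,
    method: str = "pearson",
    eps: float = DET_EPS,
) -> tuple[float, float, bool]:
    """SNAI together with the correlation log-determinant and a degeneracy
    flag (det below ``eps``, e.g. when cells do not outnumber analytes)."""
    X = _check_matrix(values, min_cells=3, min_analytes=2)
    sd = X.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = (
            [analyte_names[j] for j in zero]
            if analyte_names is not None
            else zero.tolist()
        )
        raise ValidationError(f"zero-variance analytes: {names}")
    if X.shape[0] <= X.shape[1]:
        warnings.warn(
            f"{X.shape[0]} cells for {X.shape[1]} analytes: correlation "
            "matrix is singular or near-singular; SNAI is degenerate"
        )
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 0, X)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    R = np.corrcoef(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    det = sign * np.exp(logdet)
    degenerate = not (det > eps)
    value = float("inf") if det <= 0 else float(1.0 / det)
    return value, float(logdet if sign > 0 else -np.inf), degenerate


def ic_index(
    values: np.ndarray, absolute: bool = True, eps: float = 1e-12
) -> float:
    """Mean |analyte-pair r| over mean |cell-pair r| within a cluster."""
    X = _check_matrix(values, min_cells=3, min_analytes=3)
    if np.any(X.std(axis=0) == 0):
        raise ValidationError("zero-variance analyte; Ic undefined")
    if np.any(X.std(axis=1) == 0):
        raise ValidationError("zero-variance cell; Ic undefined")
    num = _mean_offdiag(np.corrcoef(X, rowvar=False), absolute)
    den = _mean_offdiag(np.corrcoef(X, rowvar=True), absolute)
    if abs(den) < eps:
        raise ValidationError("mean cell-cell correlation is ~0; Ic undefined")
    return float(num / den)


def _mean_offdiag(R: np.ndarray, absolute: bool) -> float:
    iu = np.triu_indices_from(R, k=1)
    vals = R[iu]
    return float(np.mean(np.abs(vals) if absolute else vals))


def assign_paths(
    assignment: ClusterAssignment, module2_scores: np.ndarray
) -> dict[int, str | None]:
    """Label clusters upper/lower by the majority sign of module-2 scores.

    Convention: MITF-high cells carry negative module-2 scores, so a
    majority-negative cluster sits on the upper path.  Exact 50/50 splits
    stay unassigned with a warning.
    """
    scores = np.asarray(module2_scores, float)
    if scores.size != assignment.labels.size:
        raise ValidationError("one module-2 score per cell required")
    paths: dict[int, str | None] = {}
    for cid in assignment.cluster_ids():
        members = assignment.members(cid)
        n_neg = int(np.sum(scores[members] < 0))
        n_pos = members.size - n_neg
        if n_neg > n_pos:
            paths[cid] = "upper"
        elif n_pos > n_neg:
            paths[cid] = "lower"
        else:
            warnings.warn(f"cluster {cid}: exact 50/50 sign split; unassigned")
            paths[cid] = None
    return paths


@dataclass
class CriticalityReport:
    """Per-cluster SNAI/Ic values with path labels."""

    frame: pd.DataFrame  # cluster, day, path, n_cells, snai, logdet, ic, degenerate
    analytes_used: tuple[str, ...]
    index_used: str

    def row(self, cluster_id: int) -> pd.Series:
        sel = self.frame[self.frame["cluster"] == cluster_id]
        if sel.empty:
            raise KeyError(cluster_id)
        return sel.iloc[0]


def criticality_report(
    table: SingleCellTable,
    assignment: ClusterAssignment,
    paths: Mapping[int, str | None] | None = None,
    module2_scores: np.ndarray | None = None,
    analytes: Sequence[str] | None = None,
    ic_analytes: Sequence[str] | None = None,
    method: str = "pearson",
    index: str = "snai",
) -> CriticalityReport:
    """Compute SNAI and Ic for every cluster.

    Path labels come from ``paths`` directly or from
    :func:`assign_paths` on ``module2_scores``.  ``analytes`` (the SNAI
    set) defaults to the 10 clustering markers, which keeps cluster sizes
    above the analyte count in realistic runs — a correlation determinant
    from fewer cells than analytes is exactly singular.  ``ic_analytes``
    defaults to the same set so the two indices rank clusters on common
    variables; pass the full panel to exploit analytes SNAI cannot use.
    """
    if not table.log_space:
        raise ValidationError("criticality expects a log-space table")
    if paths is None:
        if module2_scores is None:
            raise ValidationError("provide paths or module2_scores")
        paths = assign_paths(assignment, module2_scores)
    if analytes is None:
        analytes = [m for m in CLUSTERING_MARKERS if m in table.panel.names]
        if not analytes:
            analytes = list(table.panel.names)
    if ic_analytes is None:
        ic_analytes = list(analytes)
    data = table.marker_matrix(analytes)
    ic_data = table.marker_matrix(ic_analytes)
    rows = []
    for cid in assignment.cluster_ids():
        members = assignment.members(cid)
        sub = data[members]
        entry = {
            "cluster": cid,
            "day": assignment.day_of_cluster[cid],
            "path": paths.get(cid),
            "n_cells": int(members.size),
            "snai": np.nan,
            "logdet": np.nan,
            "ic": np.nan,
            "degenerate": True,
        }
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                value, logdet, degenerate = snai_details(sub, analytes, method)
            entry.update(snai=value, logdet=logdet, degenerate=degenerate)
        except ValidationError:
            pass
        try:
            entry["ic"] = ic_index(ic_data[members])
        except ValidationError:
            pass
        rows.append(entry)
    frame = pd.DataFrame(rows)
    return CriticalityReport(
        frame=frame, analytes_used=tuple(analytes), index_used=index
    )


def tipping_cluster(
    report: CriticalityReport, path: str, index: str = "snai"
) -> int:
    """Argmax cluster of the chosen index along one path.

    Degenerate clusters (singular correlation matrices for SNAI, undefined
    Ic) are excluded; ties raise rather than silently picking one.
    """
    if index not in ("snai", "ic"):
        raise ValidationError(f"unknown index {index!r}")
    frame = report.frame
    on_path = frame[frame["path"] == path]
    if on_path.empty:
        raise ValidationError(f"no clusters on path {path!r}")
    valid = on_path[~on_path["degenerate"] & np.isfinite(on_path[index])]
    if valid.empty:
        raise ValidationError(f"all clusters on path {path!r} are degenerate")
    if len(valid) < 2:
        raise ValidationError(
            f"path {path!r} has fewer than 2 usable clusters; "
            "argmax is not meaningful"
        )
    col = valid[index].to_numpy()
    best = col.max()
    winners = valid["cluster"].to_numpy()[col == best]
    if winners.size > 1:
        raise ValidationError(
            f"tie for the {index} argmax on path {path!r}: {winners.tolist()}"
        )
    return int(winners[0])
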