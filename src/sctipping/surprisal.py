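"""Surprisal decomposition of log-level matrices.

The measured log level of analyte ``i`` in cell ``c`` is written as a
steady-state term plus a small number of deviation modules,

    ln X_i(c) = lambda_0(c) G_0i + sum_j lambda_j(c) G_ij ,

where each module couples a cell-dependent influence score ``lambda_j(c)``
to a cell-independent analyte pattern ``G_ij``.  Numerically this is the
singular value decomposition of the (uncentered) log matrix: the leading
component carries the steady state, components 2..J+1 are modules 1..J,
scores are ``u_j s_j`` (so they carry the singular value and are comparable
across cells) and loadings are the unit right-singular vectors.

Exposed statsmodels-style: ``SurprisalAnalysis(table, n_modules).fit()``
returns a :class:`SurprisalResults` with the scores, loadings, scree,
reconstruction and interpretation utilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .data import SingleCellTable, ValidationError


class SurprisalAnalysis:
    """Model object: surprisal (SVD) decomposition of a log-space table.

    Parameters
    ----------
    table:
        Log-space :class:`~sctipping.data.SingleCellTable`.
    n_modules:
        Number of deviation modules J beyond the steady state (default 2:
        one time-dependent and one path-dependent module).
    center:
        Optionally subtract the per-analyte mean before the SVD, for
        comparison with conventional PCA.  Default is the surprisal
        formalism's uncentered decomposition.
    """

    def __init__(
        self,
        table: SingleCellTable,
        n_modules: int = 2,
        center: bool = False,
    ) -> None:
        if not table.log_space:
            raise ValidationError("surprisal analysis expects log-space data")
        if not np.all(np.isfinite(table.values)):
            raise ValidationError("table contains NaN")
        m, n = table.values.shape
        if n_modules < 1:
            raise ValidationError("n_modules must be at least 1")
        if n_modules >= min(m, n):
            raise ValidationError(
                f"n_modules={n_modules} must be below min(m, n)={min(m, n)}"
            )
        self.table = table
        self.n_modules = int(n_modules)
        self.center = bool(center)

    def fit(self) -> "SurprisalResults":
        M = self.table.values
        offset = M.mean(axis=0) if self.center else np.zeros(M.shape[1])
        U, s, Vt = np.linalg.svd(M - offset, full_matrices=False)
        # Deterministic sign convention: the largest-|loading| analyte of
        # every component gets a positive loading.
        for k in range(Vt.shape[0]):
            pivot = int(np.argmax(np.abs(Vt[k])))
            if Vt[k, pivot] < 0:
                Vt[k] *= -1.0
                U[:, k] *= -1.0
        # Module 1 (component index 1) additionally points forward in time:
        # mean score on the last day exceeds the first day.
        days = self.table.days_present()
        if len(days) >= 2:
            score1 = U[:, 1] * s[1]
            first = score1[self.table.day == days[0]].mean()
            last = score1[self.table.day == days[-1]].mean()
            if last < first:
                Vt[1] *= -1.0
                U[:, 1] *= -1.0
        return SurprisalResults(model=self, _U=U, _s=s, _Vt=Vt, _offset=offset)


@dataclass
class SurprisalResults:
    """Fitted decomposition: scores, loadings and singular values."""

    model: SurprisalAnalysis
    _U: np.ndarray
    _s: np.ndarray
    _Vt: np.ndarray
    _offset: np.ndarray

    # -- core quantities -------------------------------------------------
    @property
    def singular_values(self) -> np.ndarray:
        return self._s

    @property
    def steady_state_loading(self) -> np.ndarray:
        return self._Vt[0]

    @property
    def steady_state_score(self) -> np.ndarray:
        return self._U[:, 0] * self._s[0]

    @property
    def module_loadings(self) -> np.ndarray:
        """J x n matrix of unit analyte patterns G_ij."""
        J = self.model.n_modules
        return self._Vt[1 : J + 1]

    @property
    def module_scores(self) -> np.ndarray:
        """m x J matrix of influence scores lambda_j(c) = u_j(c) s_j."""
        J = self.model.n_modules
        return self._U[:, 1 : J + 1] * self._s[1 : J + 1]

    @property
    def n_components(self) -> int:
        return self._s.size

    # -- operations ------------------------------------------------------
    def reconstruct(self, upto: int) -> np.ndarray:
        """Steady state plus the first ``upto`` modules, in log space."""
        if not 0 <= upto <= self.n_components - 1:
            raise ValidationError(
                f"upto must be in [0, {self.n_components - 1}]"
            )
        k = upto + 1  # components including the steady state
        approx = (self._U[:, :k] * self._s[:k]) @ self._Vt[:k]
        return approx + self._offset

    def scree(self) -> pd.DataFrame:
        """Singular values and their squared (variance) fractions."""
        frac = self._s**2 / float((self._s**2).sum())
        return pd.DataFrame(
            {
                "component": np.arange(self._s.size),
                "singular_value": self._s,
                "variance_fraction": frac,
            }
        )

    def marker_module_correlation(self, j: int = 2) -> pd.Series:
        """Pearson r between each analyte's log level and module ``j``'s score.

        ``j`` is 1-based (module 1 is the first deviation component).
        Zero-variance analytes get NaN with a warning.
        """
        scores = self._module_score(j)
        M = self.model.table.values
        r = np.full(M.shape[1], np.nan)
        sc = scores - scores.mean()
        denom_s = np.sqrt((sc**2).sum())
        for i in range(M.shape[1]):
            col = M[:, i] - M[:, i].mean()
            denom_c = np.sqrt((col**2).sum())
            if denom_c == 0 or denom_s == 0:
                warnings.warn(
                    f"zero variance for analyte "
                    f"{self.model.table.panel.names[i]!r}; correlation undefined"
                )
                continue
            r[i] = float(col @ sc) / (denom_c * denom_s)
        return pd.Series(r, index=list(self.model.table.panel.names), name=f"r_module{j}")

    def _module_score(self, j: int) -> np.ndarray:
        if not 1 <= j <= self.model.n_modules:
            raise ValidationError(f"module {j} not in 1..{self.model.n_modules}")
        return self.module_scores[:, j - 1]

    def quantile_groups(self, j: int = 2, q: float = 0.10) -> np.ndarray:
        return quantile_groups(self._module_score(j), q)

    def sign_boundary(self, j: int = 1):
        return sign_boundary(self._module_score(j), self.model.table.day)

    def scores_frame(self) -> pd.DataFrame:
        table = self.model.table
        df = pd.DataFrame(
            {"cell_id": list(table.cell_ids), "day": table.day}
        )
        df["lambda0"] = self.steady_state_score
        for j in range(1, self.model.n_modules + 1):
            df[f"lambda{j}"] = self.module_scores[:, j - 1]
        return df

    def loadings_frame(self) -> pd.DataFrame:
        table = self.model.table
        df = pd.DataFrame({"analyte": list(table.panel.names)})
        df["G_0"] = self.steady_state_loading
        for j in range(1, self.model.n_modules + 1):
            df[f"G_{j}"] = self.module_loadings[j - 1]
        return df

    def summary(self) -> str:
        table = self.model.table
        lines = [
            "Surprisal decomposition",
            "=======================",
            f"cells: {table.n_cells}   analytes: {table.n_analytes}   "
            f"modules: {self.model.n_modules}   centered: {self.model.center}",
            "",
            "component  singular value  variance fraction",
        ]
        scree = self.scree()
        for _, row in scree.head(self.model.n_modules + 3).iterrows():
            lines.append(
                f"{int(row['component']):>9d}  {row['singular_value']:>14.4f}"
                f"  {row['variance_fraction']:>17.5f}"
            )
        for j in range(1, self.model.n_modules + 1):
            load = self.module_loadings[j - 1]
            order = np.argsort(-np.abs(load))[:3]
            tops = ", ".join(
                f"{table.panel.names[i]} ({load[i]:+.2f})" for i in order
            )
            lines.append(f"module {j} top loadings: {tops}")
        return "\n".join(lines)


def decompose(table: SingleCellTable, n_modules: int = 2, center: bool = False) -> SurprisalResults:
    """Functional wrapper: fit a :class:`SurprisalAnalysis`."""
    return SurprisalAnalysis(table, n_modules=n_modules, center=center).fit()


# ---------------------------------------------------------------------------
# Score utilities
# ---------------------------------------------------------------------------

def quantile_groups(scores: np.ndarray, q: float = 0.10) -> np.ndarray:
    """Label the top/bottom score quantiles 'High'/'Low', the rest 'Mid'.

    Exactly ceil(q*m) cells per extreme group; ties resolved by stable cell
    order.  All-equal scores are rejected (no meaningful extremes).
    """
    scores = np.asarray(scores, float)
    if not 0.0 < q < 0.5:
        raise ValidationError("q must be in (0, 0.5)")
    m = scores.size
    n_group = int(np.ceil(q * m))
    if m < 2 or 2 * n_group > m:
        raise ValidationError(
            f"{m} cells cannot host two disjoint {q:.0%} groups"
        )
    if scores.max() == scores.min():
        raise ValidationError("all scores equal; quantile groups undefined")
    order = np.argsort(scores, kind="stable")
    labels = np.full(m, "Mid", dtype=object)
    labels[order[:n_group]] = "Low"
    labels[order[-n_group:]] = "High"
    return labels


def sign_boundary(
    scores: np.ndarray, day: np.ndarray | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Partition cells by the sign of a module score (zero counts positive).

    Returns per-cell signs (+1/-1) and per-day counts of each side — the
    boundary where a path's scores cross zero marks a cell-state transition.
    """
    scores = np.asarray(scores, float)
    signs = np.where(scores >= 0, 1, -1)
    if day is None:
        day = np.zeros(scores.size, dtype=int)
    day = np.asarray(day)
    rows = []
    for d in sorted(set(day.tolist())):
        sel = day == d
        rows.append(
            {
                "day": d,
                "n_negative": int(np.sum(signs[sel] < 0)),
                "n_nonnegative": int(np.sum(signs[sel] > 0)),
            }
        )
    return signs, pd.DataFrame(rows)


def align_scores(estimated: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Best orthogonal alignment of estimated score columns to a reference.

    SVD scores are identified only up to rotation/reflection within a
    near-degenerate subspace; recovery is therefore judged after the best
    orthogonal (Procrustes) alignment of the J estimated columns onto the
    planted ones.
    """
    estimated = np.asarray(estimated, float)
    reference = np.asarray(reference, float)
    R, _ = orthogonal_procrustes(estimated, reference)
    return estimated @ R


def orient_scores_by_marker(
    scores: np.ndarray, marker_levels: np.ndarray
) -> np.ndarray:
    """Flip a score vector so it correlates non-positively with a marker.

    Used by the pipeline to pin the path-module sign convention to the
    lineage marker (MITF-high cells get negative module-2 scores).
    """
    scores = np.asarray(scores, float)
    marker = np.asarray(marker_levels, float)
    r = np.corrcoef(scores, marker)[0, 1]
    return -scores if r > 0 else scores.copy()
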