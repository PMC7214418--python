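"""Per-cluster Spearman correlation networks with Bonferroni filtering.

Within a cluster of cells, every unordered analyte pair gets a Spearman
rank correlation and a two-sided p-value; an edge is kept when its raw
p-value survives a per-network Bonferroni correction over all
p(p-1)/2 pairs.  Node importance is summarized by the degree (number of
significant incident edges) and the hub score (principal-eigenvector
centrality of the |rho|-weighted significant adjacency), both rescaled to
[0, 1] for side-by-side comparison across networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ValidationError

HUB_TOL = 1e-12
HUB_MAX_ITER = 100_000


@dataclass
class CorrelationNetwork:
    analytes: tuple[str, ...]
    rho: np.ndarray          # p x p Spearman correlations (NaN where undefined)
    p_raw: np.ndarray        # p x p two-sided p-values
    significant: np.ndarray  # p x p boolean, Bonferroni-filtered
    alpha: float
    n_tests: int
    n_cells: int
    cluster_id: int | None = None

    @property
    def n_analytes(self) -> int:
        return len(self.analytes)

    def edges_frame(self) -> pd.DataFrame:
        rows = []
        p = self.n_analytes
        for i in range(p):
            for j in range(i + 1, p):
                rows.append(
                    {
                        "analyte_a": self.analytes[i],
                        "analyte_b": self.analytes[j],
                        "rho": self.rho[i, j],
                        "p_raw": self.p_raw[i, j],
                        "significant": bool(self.significant[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def metrics_frame(self) -> pd.DataFrame:
        degree = node_degree(self)
        hub = hub_score(self)
        return pd.DataFrame(
            {
                "analyte": list(self.analytes),
                "degree": degree,
                "hub": hub,
                "degree_scaled": rescale_01(degree.astype(float)),
                "hub_scaled": rescale_01(hub),
            }
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.analytes)
        p = self.n_analytes
        for i in range(p):
            for j in range(i + 1, p):
                if self.significant[i, j]:
                    g.add_edge(
                        self.analytes[i],
                        self.analytes[j],
                        rho=float(self.rho[i, j]),
                        weight=float(abs(self.rho[i, j])),
                    )
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def _spearman_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t-approximation with n-2 degrees of freedom."""
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - rho**2
        t = rho * np.sqrt((n - 2) / denom)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return p


def _spearman_permutation_pvalues(
    X: np.ndarray, rho: np.ndarray, n_perm: int, seed: int
) -> np.ndarray:
    """Exact-style permutation p-values (small-n alternative), seeded."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    pvals = np.ones((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            obs = abs(rho[i, j])
            if not np.isfinite(obs):
                continue
            count = 0
            ri = ranks[:, i]
            rj = ranks[:, j]
            for _ in range(n_perm):
                perm = rng.permutation(rj)
                r = np.corrcoef(ri, perm)[0, 1]
                if abs(r) >= obs - 1e-15:
                    count += 1
            pvals[i, j] = pvals[j, i] = (count + 1) / (n_perm + 1)
    np.fill_diagonal(pvals, 0.0)
    return pvals


def correlation_network(
    values: np.ndarray,
    analyte_names: Sequence[str],
    alpha: float = 0.05,
    p_method: str = "t",
    n_perm: int = 10_000,
    seed: int = 0,
    cluster_id: int | None = None,
) -> CorrelationNetwork:
    """Bonferroni-filtered Spearman network over a cells x analytes matrix.

    Constant analytes yield undefined correlations: their pairs are kept in
    the Bonferroni family but marked non-significant (conservative), with a
    warning.
    """
    X = np.asarray(values, float)
    if X.ndim != 2:
        raise ValidationError("expected a cells x analytes matrix")
    n, p = X.shape
    if n < 5:
        raise ValidationError("need at least 5 cells for a correlation network")
    if p < 2:
        raise ValidationError("need at least 2 analytes")
    if len(analyte_names) != p:
        raise ValidationError("one analyte name per column required")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(X).statistic
    if p == 2:  # spearmanr returns a scalar for two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    constant = np.flatnonzero(X.std(axis=0) == 0)
    if constant.size:
        warnings.warn(
            f"constant analytes {[analyte_names[i] for i in constant]}: "
            "their correlations are undefined and left non-significant"
        )
    if p_method == "t":
        p_raw = _spearman_pvalues(rho, n)
    elif p_method == "permutation":
        p_raw = _spearman_permutation_pvalues(X, rho, n_perm, seed)
    else:
        raise ValidationError(f"unknown p_method {p_method!r}")
    np.fill_diagonal(p_raw, 0.0)
    n_tests = p * (p - 1) // 2
    threshold = alpha / n_tests
    with np.errstate(invalid="ignore"):
        significant = (p_raw <= threshold) & np.isfinite(rho)
    np.fill_diagonal(significant, False)
    return CorrelationNetwork(
        analytes=tuple(analyte_names),
        rho=rho,
        p_raw=p_raw,
        significant=significant,
        alpha=alpha,
        n_tests=n_tests,
        n_cells=n,
        cluster_id=cluster_id,
    )


def node_degree(network: CorrelationNetwork) -> np.ndarray:
    """Number of significant incident edges per analyte."""
    return network.significant.sum(axis=1).astype(int)


def hub_score(network: CorrelationNetwork) -> np.ndarray:
    """Principal-eigenvector centrality of the |rho|-weighted significant
    adjacency, by power iteration from the degree vector.

    Disconnected networks are scored globally: components off the dominant
    eigenvector get (near-)zero scores.  Networks with no significant edge
    return all zeros with a warning.
    """
    A = np.where(network.significant, np.abs(network.rho), 0.0)
    A = np.nan_to_num(A, nan=0.0)
    if not np.any(A > 0):
        warnings.warn("no significant edges; hub scores are all zero")
        return np.zeros(network.n_analytes)
    # Positive diagonal shift: eigenvectors are unchanged but the dominant
    # eigenvalue becomes unique in magnitude, so the iteration also
    # converges on bipartite graphs (e.g. stars), whose unshifted spectrum
    # is symmetric (+/- lambda_max).
    shift = float(A.sum(axis=1).max())
    A_shifted = A + shift * np.eye(A.shape[0])
    x = A.sum(axis=1)  # degree-like start, nonnegative
    x = x / np.linalg.norm(x)
    for _ in range(HUB_MAX_ITER):
        x_new = A_shifted @ x
        norm = np.linalg.norm(x_new)
        if norm == 0:  # pragma: no cover - A has a positive entry
            return np.zeros(network.n_analytes)
        x_new /= norm
        if np.max(np.abs(x_new - x)) < HUB_TOL:
            x = x_new
            break
        x = x_new
    return np.abs(x)


def rescale_01(metric: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); all-equal input maps to zeros with warning."""
    metric = np.asarray(metric, float)
    if metric.size == 0:
        raise ValidationError("cannot rescale an empty metric vector")
    lo, hi = float(metric.min()), float(metric.max())
    if hi == lo:
        if metric.size > 1:
            warnings.warn("all metric values equal; rescaled to zeros")
        return np.zeros_like(metric)
    return (metric - lo) / (hi - lo)
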