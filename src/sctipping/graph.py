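"""Sequential k-NN graph over a time course of single-cell snapshots.

Cells are linked to their nearest same-day neighbours and to their nearest
neighbours in each adjacent day (Euclidean distance in log-analyte space),
giving a FLOW-MAP-style graph in which position along the graph tracks both
treatment time and cell state.  Directed k-NN lists are merged into one
simple undirected graph; edges between non-adjacent days never occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
from sklearn.neighbors import NearestNeighbors

from .data import SingleCellTable, ValidationError

EDGE_EPS = 1e-8  # weight = 1 / (distance + EDGE_EPS)


@dataclass
class CellGraph:
    """Undirected cell graph with day attributes and optional 2-D layout."""

    graph: nx.Graph
    parameters: dict
    layout: dict | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def set_overlay(self, name: str, values_by_cell: dict) -> None:
        """Attach per-node values (analyte level, module score, ...)."""
        nx.set_node_attributes(self.graph, values_by_cell, name)

    def edges_frame(self):
        import pandas as pd

        rows = [
            {
                "cell_a": a,
                "cell_b": b,
                "distance": d["distance"],
                "weight": d["weight"],
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["cell_a", "cell_b", "distance", "weight"])

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        if self.layout is not None:
            for node, (x, y) in self.layout.items():
                g.nodes[node]["x"] = float(x)
                g.nodes[node]["y"] = float(y)
        nx.write_graphml(g, path)


def build_graph(
    table: SingleCellTable, k_intra: int = 5, k_inter: int = 3
) -> CellGraph:
    """Mutual sequential k-NN graph on a log-space table.

    Every cell is joined to its ``k_intra`` nearest same-day cells and its
    ``k_inter`` nearest cells in each adjacent day; the union of these
    directed lists is returned as a simple undirected graph.
    """
    if not table.log_space:
        raise ValidationError("graph building expects a log-space table")
    if k_intra < 1 or k_inter < 1:
        raise ValidationError("k_intra and k_inter must be at least 1")
    days = table.days_present()
    if len(days) < 2:
        raise ValidationError("need at least 2 days to build a sequential graph")
    idx_by_day = {d: np.flatnonzero(table.day == d) for d in days}
    for d in days:
        if idx_by_day[d].size < k_intra + 1:
            raise ValidationError(
                f"day {d} has {idx_by_day[d].size} cells, fewer than "
                f"k_intra+1={k_intra + 1}; use a smaller k_intra"
            )
    for a, b in zip(days[:-1], days[1:]):
        if min(idx_by_day[a].size, idx_by_day[b].size) < k_inter:
            raise ValidationError(
                f"adjacent days {a},{b} have fewer than k_inter={k_inter} "
                "cells; use a smaller k_inter"
            )

    g = nx.Graph()
    for i, cid in enumerate(table.cell_ids):
        g.add_node(cid, day=int(table.day[i]))

    def _add(src_idx: np.ndarray, dst_idx: np.ndarray, k: int, same: bool) -> None:
        nn = NearestNeighbors(n_neighbors=k + (1 if same else 0))
        nn.fit(table.values[dst_idx])
        dist, nbr = nn.kneighbors(table.values[src_idx])
        for row, i_src in enumerate(src_idx):
            for col in range(dist.shape[1]):
                i_dst = dst_idx[nbr[row, col]]
                if i_dst == i_src:
                    continue
                a, b = table.cell_ids[i_src], table.cell_ids[i_dst]
                d = float(dist[row, col])
                if not g.has_edge(a, b):
                    g.add_edge(a, b, distance=d, weight=1.0 / (d + EDGE_EPS))

    for d in days:
        _add(idx_by_day[d], idx_by_day[d], k_intra, same=True)
    for a, b in zip(days[:-1], days[1:]):
        _add(idx_by_day[a], idx_by_day[b], k_inter, same=False)
        _add(idx_by_day[b], idx_by_day[a], k_inter, same=False)

    return CellGraph(
        graph=g,
        parameters={
            "k_intra": k_intra,
            "k_inter": k_inter,
            "metric": "euclidean",
        },
    )


def layout(cell_graph: CellGraph, seed: int = 0, iterations: int = 50) -> dict:
    """Deterministic force-directed 2-D layout (seeded spring embedding)."""
    g = cell_graph.graph
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot lay out an empty graph")
    if g.number_of_nodes() == 1:
        node = next(iter(g.nodes))
        pos = {node: np.zeros(2)}
    else:
        pos = nx.spring_layout(
            g, seed=seed, iterations=iterations, weight="weight"
        )
    cell_graph.layout = {n: np.asarray(p, float) for n, p in pos.items()}
    cell_graph.parameters.update({"layout_seed": seed, "layout_iterations": iterations})
    return cell_graph.layout


def plot_graph(cell_graph: CellGraph, color_by: str = "day", ax=None):
    """Scatter the laid-out graph colored by a node attribute (figure aid)."""
    import matplotlib.pyplot as plt

    if cell_graph.layout is None:
        layout(cell_graph)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    pos = cell_graph.layout
    for a, b in cell_graph.graph.edges():
        xa, ya = pos[a]
        xb, yb = pos[b]
        ax.plot([xa, xb], [ya, yb], color="0.85", lw=0.3, zorder=1)
    xs = np.array([pos[n][0] for n in cell_graph.graph.nodes])
    ys = np.array([pos[n][1] for n in cell_graph.graph.nodes])
    colors = [
        cell_graph.graph.nodes[n].get(color_by, 0.0)
        for n in cell_graph.graph.nodes
    ]
    sc = ax.scatter(xs, ys, c=colors, s=12, cmap="viridis", zorder=2)
    ax.figure.colorbar(sc, ax=ax, label=color_by)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
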