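"""The time-series graph: lag-specific directed links with test statistics.

A link ``(i, tau, j)`` with ``tau >= 1`` states that component ``i`` at time
``t - tau`` directly influences component ``j`` at time ``t`` given the rest
of the past.  Lag-0 (contemporaneous) links never appear — they are excluded
by assumption.  The graph can be exported as a TSV edge list, as an
aggregated "summary" digraph collapsing lags, or as the fully time-resolved
digraph, in GraphML or DOT form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["TimeSeriesGraph", "write_dot"]


@dataclass
class TimeSeriesGraph:
    """Discovered lag-specific links with statistics for all tested links.

    Arrays are indexed ``[target, source, lag]`` with lag 0..tau_max;
    ``link_matrix`` marks the retained links (p <= alpha, lag >= 1).
    """

    val_matrix: np.ndarray
    p_matrix: np.ndarray
    tau_max: int
    alpha: float
    labels: list[str]
    link_matrix: np.ndarray | None = None
    n_eff: int | None = None
    n_ci_tests: dict | None = None
    parents: "object | None" = None  # ParentSets from the discovery run

    def __post_init__(self) -> None:
        self.val_matrix = np.asarray(self.val_matrix, dtype=float)
        self.p_matrix = np.asarray(self.p_matrix, dtype=float)
        if self.val_matrix.shape != self.p_matrix.shape:
            raise ValueError("val_matrix and p_matrix shapes differ")
        n = self.val_matrix.shape[0]
        if self.val_matrix.shape != (n, n, self.tau_max + 1):
            raise ValueError(
                f"expected shape {(n, n, self.tau_max + 1)}, got {self.val_matrix.shape}"
            )
        if self.link_matrix is None:
            self.link_matrix = self.p_matrix <= self.alpha
        self.link_matrix = np.asarray(self.link_matrix, dtype=bool)
        self.link_matrix[:, :, 0] = False  # no contemporaneous links, ever
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} components")

    @property
    def n_vars(self) -> int:
        return self.val_matrix.shape[0]

    def links(self):
        """Yield retained links as ``(source, lag, target, val, p)``, sorted."""
        for j, i, tau in sorted(
            map(tuple, np.argwhere(self.link_matrix)), key=lambda x: (x[1], x[0], x[2])
        ):
            yield i, tau, j, float(self.val_matrix[j, i, tau]), float(
                self.p_matrix[j, i, tau]
            )

    def n_links(self) -> int:
        return int(self.link_matrix.sum())

    def parents_of(self, j: int) -> list[tuple[int, int]]:
        """Discovered parents of target ``j`` as (source, lag) pairs."""
        return [
            (int(i), int(tau))
            for i, tau in np.argwhere(self.link_matrix[j])
        ]

    # -- exports ----------------------------------------------------------
    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            (self.labels[i], self.labels[j], tau, val, p)
            for i, tau, j, val, p in self.links()
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "lag", "val", "p_value"]
        )

    def write_edges_tsv(self, path) -> None:
        self.to_edge_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def summary_digraph(self) -> nx.DiGraph:
        """Aggregated graphical model: one edge per (source, target), lags listed."""
        G = nx.DiGraph()
        G.add_nodes_from(self.labels)
        for i, tau, j, val, p in self.links():
            u, v = self.labels[i], self.labels[j]
            if G.has_edge(u, v):
                e = G[u][v]
                e["lags"] = e["lags"] + f",{tau}"
                if abs(val) > abs(e["val"]):
                    e["val"] = val
                e["min_p"] = min(e["min_p"], p)
            else:
                G.add_edge(u, v, lags=str(tau), val=val, min_p=p)
        return G

    def time_series_digraph(self, window: int | None = None) -> nx.DiGraph:
        """Time-resolved graph over a window of time offsets 0..window."""
        if window is None:
            window = self.tau_max
        G = nx.DiGraph()
        for off in range(window + 1):
            for lab in self.labels:
                G.add_node(f"{lab}@t-{off}" if off else f"{lab}@t", var=lab, offset=off)
        for i, tau, j, val, p in self.links():
            for off in range(window - tau + 1):
                u = f"{self.labels[i]}@t-{off + tau}"
                v = f"{self.labels[j]}@t-{off}" if off else f"{self.labels[j]}@t"
                G.add_edge(u, v, val=val, lag=tau)
        return G

    def write_graphml(self, path, time_resolved: bool = False) -> None:
        G = self.time_series_digraph() if time_resolved else self.summary_digraph()
        nx.write_graphml(G, path)

    def write_dot(self, path, time_resolved: bool = False) -> None:
        G = self.time_series_digraph() if time_resolved else self.summary_digraph()
        write_dot(G, path)


def write_dot(G: nx.DiGraph, path) -> None:
    """Minimal DOT export (nodes, directed edges, scalar attributes)."""
    def q(s: object) -> str:
        return '"' + str(s).replace('"', r"\"") + '"'

    lines = ["digraph {"]
    for node, attrs in G.nodes(data=True):
        astr = " ".join(f"{k}={q(v)}" for k, v in sorted(attrs.items()))
        lines.append(f"  {q(node)} [{astr}];" if astr else f"  {q(node)};")
    for u, v, attrs in G.edges(data=True):
        astr = " ".join(
            f"{k}={q(f'{val:.6g}' if isinstance(val, float) else val)}"
            for k, val in sorted(attrs.items())
        )
        lines.append(
            f"  {q(u)} -> {q(v)} [{astr}];" if astr else f"  {q(u)} -> {q(v)};"
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
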