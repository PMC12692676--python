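"""Lipid–lipid and lipid–trait Pearson correlation networks.

Marker lipids and meat-quality traits are joined into one correlation
matrix; pairs passing both an |r| threshold and a p-value cutoff become
signed edges of an undirected graph (positive edges are the "red lines",
negative the "blue" ones of the usual network plots). A hierarchical
ordering of the matrix (average linkage on 1−r distance) is provided for
heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

__all__ = [
    "pairwise_pearson",
    "build_network",
    "export_graph",
    "read_graph",
    "heatmap_order",
    "critical_r",
]


def pairwise_pearson(X: pd.DataFrame, Y: pd.DataFrame | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r and two-sided p between columns of X (and Y).

    Columns are variables, rows are shared samples; missing cells are
    pairwise-deleted. p-values come from the exact t transform
    ``t = r·sqrt((n−2)/(1−r²))``. Pairs with fewer than three shared
    observations or a zero-variance member are NaN (undefined), never a
    silent zero.
    """
    if Y is None:
        Y = X
    joined = X.join(Y, how="inner", lsuffix="", rsuffix="__y") \
        if X is not Y and not X.columns.intersection(Y.columns).empty else None
    xa = X.to_numpy(dtype=float)
    ya = Y.to_numpy(dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share the sample axis")
    del joined

    r = pd.DataFrame(np.nan, index=X.columns, columns=Y.columns)
    p = pd.DataFrame(np.nan, index=X.columns, columns=Y.columns)
    for i, cx in enumerate(X.columns):
        for j, cy in enumerate(Y.columns):
            a, b = xa[:, i], ya[:, j]
            ok = ~np.isnan(a) & ~np.isnan(b)
            n = int(ok.sum())
            if n < 3:
                continue
            aa, bb = a[ok], b[ok]
            if aa.std() == 0 or bb.std() == 0:
                continue
            rij = float(np.corrcoef(aa, bb)[0, 1])
            rij = max(-1.0, min(1.0, rij))
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((n - 2) / (1.0 - rij * rij))
                pij = float(2.0 * stats.t.sf(abs(t), n - 2))
            r.loc[cx, cy] = rij
            p.loc[cx, cy] = pij
    return r, p


def critical_r(n: int, alpha: float = 0.05) -> float:
    """|r| above which an independent pair is significant at level alpha."""
    if n < 3:
        raise ValueError("need n >= 3")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(np.sqrt(t * t / (t * t + n - 2)))


def build_network(r: pd.DataFrame, p: pd.DataFrame,
                  r_min: float = 0.7, p_max: float = 0.05,
                  kinds: dict[str, str] | None = None) -> nx.Graph:
    """Threshold the correlation matrices into an undirected signed graph.

    Edges are exactly the unordered pairs with ``|r| >= r_min`` and
    ``p <= p_max``; undefined (NaN) pairs never form edges. Node attribute
    ``kind`` (e.g. lipid vs trait) comes from ``kinds``; edge attributes are
    ``r``, ``p`` and ``sign``.
    """
    if r.shape != p.shape:
        raise ValueError("r and p matrices must be conformable")
    g = nx.Graph()
    nodes = list(dict.fromkeys(list(r.index) + list(r.columns)))
    for node in nodes:
        g.add_node(node, kind=(kinds or {}).get(node, "lipid"))
    for i in r.index:
        for j in r.columns:
            if i == j or g.has_edge(i, j):
                continue
            rij = r.loc[i, j]
            pij = p.loc[i, j]
            if pd.isna(rij) or pd.isna(pij):
                continue
            if abs(rij) >= r_min and pij <= p_max:
                g.add_edge(i, j, r=float(rij), p=float(pij),
                           sign=1 if rij >= 0 else -1)
    return g


def export_graph(graph: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the network as GraphML or an edge-list CSV."""
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "csv":
        rows = [{"source": u, "target": v, "r": d["r"], "p": d["p"],
                 "sign": d["sign"]}
                for u, v, d in sorted(graph.edges(data=True))]
        pd.DataFrame(rows, columns=["source", "target", "r", "p", "sign"]
                     ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_graph(path, fmt: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`export_graph`."""
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "csv":
        df = pd.read_csv(path)
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.source, row.target, r=float(row.r),
                       p=float(row.p), sign=int(row.sign))
        return g
    raise ValueError(f"unknown format {fmt!r}")


def heatmap_order(r: pd.DataFrame) -> list:
    """Row/column order from average-linkage clustering of 1−r distance.

    Expects a square symmetric correlation matrix; NaNs are treated as zero
    correlation for ordering purposes only.
    """
    if r.shape[0] != r.shape[1]:
        raise ValueError("heatmap ordering needs a square matrix")
    if r.shape[0] < 3:
        return list(r.index)
    d = 1.0 - r.fillna(0.0).to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    order = leaves_list(average(squareform(d, checks=False)))
    return [r.index[i] for i in order]
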