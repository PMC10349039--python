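"""Nodal graph-theory measures used to characterize a region's hub status.

Conventions follow the Brain Connectivity Toolbox: shortest-path lengths for
betweenness use the inverse weight of each link, betweenness is reported as
unnormalized pair counts, and the weighted clustering coefficient is the
Onnela geometric-mean variant (weights rescaled by the network maximum).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .types import Connectome


def _graph(conn: Connectome, length: bool = False) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(conn.n_nodes))
    a = conn.adjacency
    iu, ju = np.nonzero(np.triu(a, k=1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        w = float(a[i, j])
        attrs = {"weight": w}
        if length:
            attrs["length"] = 1.0 / w
        g.add_edge(i, j, **attrs)
    return g


def degree_strength(conn: Connectome) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted degree and weighted strength per node."""
    return conn.degrees(), conn.strengths()


def betweenness(conn: Connectome) -> np.ndarray:
    """Weighted shortest-path betweenness, edge length 1/weight, unnormalized.

    Unreachable pairs contribute nothing; equal-length shortest paths split
    the pair count fractionally.
    """
    if np.any(conn.adjacency < 0):
        raise ValueError("negative weights are not allowed")
    g = _graph(conn, length=True)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(conn.n_nodes)])


def clustering(conn: Connectome) -> np.ndarray:
    """Weighted clustering coefficient (Onnela geometric-mean form).

    ``c_i = 2 / (k_i (k_i - 1)) * sum_{jk} (w'_ij w'_ik w'_jk)^(1/3)`` with
    weights rescaled by the largest weight in the network; nodes with degree
    below 2 get 0.
    """
    g = _graph(conn)
    cc = nx.clustering(g, weight="weight")
    return np.array([cc[i] for i in range(conn.n_nodes)])


def node_metrics_table(conn: Connectome) -> pd.DataFrame:
    """All nodal metrics for one connectome, indexed by region label."""
    deg, stren = degree_strength(conn)
    return pd.DataFrame(
        {
            "degree": deg,
            "strength": stren,
            "betweenness": betweenness(conn),
            "clustering": clustering(conn),
        },
        index=pd.Index(conn.node_ids, name="region"),
    )


def cohort_metrics_long(
    cohort: list[Connectome], participant_ids: list[str]
) -> pd.DataFrame:
    """Long-format (participant, region, metric, value) table over a cohort."""
    frames = []
    for pid, conn in zip(participant_ids, cohort):
        t = node_metrics_table(conn).reset_index()
        t = t.melt(id_vars="region", var_name="metric", value_name="value")
        t.insert(0, "participant", pid)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
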