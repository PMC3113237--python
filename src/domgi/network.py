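"""Topology of the domain genetic-interaction network.

Nodes are domains, edges are significant domain genetic interactions
(self-edges allowed: a domain family can interact with itself across two
proteins).  The summary statistics are the usual small-world/scale-free
diagnostics: mean connectivity, mean shortest path within components,
mean local clustering, and the exponent of a power-law fit to the degree
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import optimize, special

from .io import canonical_pair

__all__ = [
    "NetworkSummary",
    "build_network",
    "summarize",
    "degree_distribution",
    "fit_powerlaw_exponent",
]


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    avg_connectivity: float
    max_degree: int
    max_degree_node: str
    avg_shortest_path: float
    avg_clustering: float
    powerlaw_exponent: float

    def as_dict(self) -> dict[str, object]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_connectivity": self.avg_connectivity,
            "max_degree": self.max_degree,
            "max_degree_node": self.max_degree_node,
            "avg_shortest_path": self.avg_shortest_path,
            "avg_clustering": self.avg_clustering,
            "powerlaw_exponent": self.powerlaw_exponent,
        }


def build_network(pairs: Iterable[tuple[str, str]]) -> nx.Graph:
    """Undirected simple graph with one edge per significant domain pair.

    Duplicate and orientation-swapped inputs collapse to a single edge;
    (d, d) pairs become self-loops.
    """
    graph = nx.Graph()
    for a, b in pairs:
        graph.add_edge(*canonical_pair(a, b))
    return graph


def degree_distribution(graph: nx.Graph) -> dict[int, float]:
    """Empirical degree distribution P(k); a self-loop adds 2 to its node."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    n = graph.number_of_nodes()
    dist: dict[int, float] = {}
    for _, k in graph.degree():
        dist[k] = dist.get(k, 0.0) + 1.0 / n
    return dict(sorted(dist.items()))


def fit_powerlaw_exponent(
    distribution: Mapping[int, float], method: str = "ols"
) -> float:
    """Exponent gamma of P(k) ~ k^-gamma from a degree distribution.

    ``ols`` (default) regresses log10 P(k) on log10 k over the unbinned
    points with k >= 1 and P(k) > 0 and returns the negated slope,
    mirroring a straight-line fit on the log-log plot.  ``mle`` maximizes
    the discrete power-law (zeta) likelihood treating the distribution as
    empirical frequencies over k >= k_min.
    """
    pts = [(k, p) for k, p in distribution.items() if k >= 1 and p > 0]
    if len(pts) < 2:
        raise ValueError("need >= 2 distinct positive degrees to fit")
    ks = np.array([k for k, _ in pts], dtype=float)
    ps = np.array([p for _, p in pts], dtype=float)
    if method == "ols":
        slope, _ = np.polyfit(np.log10(ks), np.log10(ps), 1)
        return float(-slope)
    if method == "mle":
        kmin = ks.min()
        weights = ps / ps.sum()
        mean_log = float(np.sum(weights * np.log(ks)))

        def nll(gamma: float) -> float:
            # zeta(gamma, kmin) = sum_{k>=kmin} k^-gamma (Hurwitz form)
            return gamma * mean_log + math.log(special.zeta(gamma, kmin))

        res = optimize.minimize_scalar(nll, bounds=(1.0001, 20.0), method="bounded")
        return float(res.x)
    raise ValueError(f"unknown method {method!r}")


def summarize(graph: nx.Graph, powerlaw_method: str = "ols") -> NetworkSummary:
    """Compute the small-world/scale-free summary of the domain network.

    Average shortest path is taken over all connected ordered node pairs
    within components (self distances excluded); self-loops count toward
    degree but are ignored for paths and clustering; nodes of degree < 2
    contribute 0 to mean clustering.  The power-law exponent is NaN when
    the degree distribution has fewer than two usable points.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    degrees = dict(graph.degree())
    max_degree_node = min(degrees, key=lambda v: (-degrees[v], v))

    simple = graph.copy()
    simple.remove_edges_from(nx.selfloop_edges(simple))
    dist_sum = 0.0
    dist_n = 0
    for _, lengths in nx.all_pairs_shortest_path_length(simple):
        for target, d in lengths.items():
            if d > 0:
                dist_sum += d
                dist_n += 1
    avg_path = dist_sum / dist_n if dist_n else math.nan
    avg_clust = nx.average_clustering(simple) if simple.number_of_nodes() else math.nan

    try:
        exponent = fit_powerlaw_exponent(
            degree_distribution(graph), method=powerlaw_method
        )
    except ValueError:
        exponent = math.nan

    return NetworkSummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        avg_connectivity=2.0 * n_edges / n_nodes,
        max_degree=degrees[max_degree_node],
        max_degree_node=max_degree_node,
        avg_shortest_path=avg_path,
        avg_clustering=float(avg_clust),
        powerlaw_exponent=exponent,
    )
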