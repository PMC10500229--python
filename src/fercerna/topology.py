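"""Network topology: centralities, pivotal-lncRNA screening, scale-freeness.

Hub screening uses three node-centrality measures on the undirected,
unweighted ceRNA graph:

* degree - number of incident edges;
* betweenness - unnormalised shortest-path betweenness (each unordered
  pair of other nodes counted once, endpoints excluded, credit split
  equally among equally short paths);
* closeness - harmonic closeness by default, the sum of reciprocal
  shortest-path distances to every reachable other node.  The classic
  per-component variant (n_reachable / sum of distances) is available
  behind a flag; harmonic is the default because it is the common
  convention producing closeness values above 1 for well-connected hubs.

A lncRNA is *pivotal* when it sits in the top-k (default 5) under all
three measures simultaneously.  Scale-freeness is checked the pragmatic
way: ordinary least squares of log10 node-count on log10 degree over the
degree histogram, reporting the power-law coefficients and the R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cerna import CeRNANetwork, build_network

CENTRALITY_METRICS = ("degree", "betweenness", "closeness")


def centrality_table(
    network: CeRNANetwork, closeness: str = "harmonic"
) -> pd.DataFrame:
    """Degree, betweenness and closeness for every node of the network.

    Disconnected graphs are handled per component: unreachable pairs
    contribute nothing to betweenness or closeness.
    """
    if closeness not in ("harmonic", "classic"):
        raise ValueError(f"closeness must be 'harmonic' or 'classic', got {closeness!r}")
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    betw = nx.betweenness_centrality(g, normalized=False)
    if closeness == "harmonic":
        close = nx.harmonic_centrality(g)
    else:
        close = nx.closeness_centrality(g, wf_improved=False)
    rows = [
        (n, g.nodes[n]["node_class"], g.degree(n), betw[n], close[n])
        for n in g.nodes
    ]
    return pd.DataFrame(
        rows, columns=["node", "node_class", "degree", "betweenness", "closeness"]
    )


def top_k_with_ties(values: Mapping[str, float], k: int) -> set[str]:
    """Ids of the k largest values; everything tying the k-th value included."""
    if k <= 0:
        raise ValueError("k must be positive")
    if len(values) <= k:
        return set(values)
    cutoff = sorted(values.values(), reverse=True)[k - 1]
    return {n for n, v in values.items() if v >= cutoff}


def intersect_top_ranked(
    ranked: Mapping[str, Mapping[str, float]], k: int = 5
) -> set[str]:
    """Cross-tabulation screen: ids in the top-k of every ranked metric."""
    out: set[str] | None = None
    for metric, values in ranked.items():
        top = top_k_with_ties(values, k)
        out = top if out is None else out & top
    return out if out is not None else set()


def pivotal_lncrnas(table: pd.DataFrame, k: int = 5) -> set[str]:
    """Nominate pivotal lncRNAs: top-k intersection across all metrics.

    ``table`` is a centrality table (see :func:`centrality_table`);
    only rows with ``node_class == "lncRNA"`` take part.  Ties at the
    k-th ranked value are all included, so the result is invariant under
    row permutation.  Fewer than k lncRNAs: all of them are used, with a
    warning.
    """
    lnc = table[table["node_class"] == "lncRNA"]
    if len(lnc) < k:
        warnings.warn(
            f"only {len(lnc)} lncRNAs available for a top-{k} screen; using all"
        )
    ranked = {
        metric: dict(zip(lnc["node"], lnc[metric])) for metric in CENTRALITY_METRICS
    }
    return intersect_top_ranked(ranked, k=k)


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit n(k) ~ a * k^b of the degree histogram (log-log)."""

    a: float
    b: float
    r_squared: float


def fit_power_law_histogram(
    degrees_k: Sequence[float], counts_n: Sequence[float]
) -> PowerLawFit:
    """OLS of log10 count on log10 degree over (k, n(k)) histogram points."""
    k = np.asarray(degrees_k, dtype=float)
    n = np.asarray(counts_n, dtype=float)
    if k.size < 2 or np.unique(k).size < 2:
        raise ValueError("power-law fit needs >=2 distinct degree values")
    if np.any(k <= 0) or np.any(n <= 0):
        raise ValueError("histogram points must be positive")
    x, y = np.log10(k), np.log10(n)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(a=10.0**intercept, b=slope, r_squared=r2)


def fit_power_law(network: CeRNANetwork) -> PowerLawFit:
    """Fit the degree distribution of the network; see module docstring.

    The histogram counts nodes per degree k >= 1 (empty degree bins are
    skipped, as is degree 0, which has no log).
    """
    degs = [d for _, d in network.graph.degree() if d >= 1]
    ks, ns = np.unique(degs, return_counts=True)
    return fit_power_law_histogram(ks, ns)


def extract_subnetwork(network: CeRNANetwork, pivotal: Iterable[str]) -> CeRNANetwork:
    """Induce the sub-network of triads whose lncRNA is pivotal.

    Nodes and edges are rebuilt from the retained triads, so every edge
    of the result still belongs to a triad.
    """
    pivotal = set(pivotal)
    lnc_nodes = {
        n for n, d in network.graph.nodes(data=True) if d["node_class"] == "lncRNA"
    }
    stray = pivotal - lnc_nodes
    if stray:
        raise ValueError(f"pivotal ids not lncRNA nodes of the network: {sorted(stray)}")
    if not pivotal:
        warnings.warn("empty pivotal set; sub-network is empty")
    keep = network.triads[network.triads["lncrna"].isin(pivotal)]
    fc = {n: d["log2fc"] for n, d in network.graph.nodes(data=True)}
    return build_network(keep, log2fc=fc)
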