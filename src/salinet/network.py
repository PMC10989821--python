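"""Co-occurrence network construction and topology.

Networks are built per salinity group: all-pairs Pearson correlation of the
CLR-transformed abundances across the group's samples, keeping an edge
wherever |r| meets a uniform threshold.  Both signs are retained (the sign
is stored on the edge); taxa left without any edge are excluded from the
node set.  Topology follows the usual molecular-ecological-network summary:
node/link counts, average degree, average clustering, density, Krackhardt
connectedness, greedy-modularity partition, and the R-squared of a log-log
power-law fit to the degree distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def build_network(
    clr_matrix: pd.DataFrame,
    threshold: float,
    group_salinity: float | None = None,
    group_id: str | None = None,
) -> nx.Graph:
    """Build a co-occurrence network from a taxa x samples CLR matrix.

    Edges connect taxon pairs with |Pearson r| >= threshold across the
    group's samples; isolated taxa are excluded.  Taxa with a constant CLR
    vector (undefined correlations) are excluded with a warning.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if clr_matrix.shape[1] < 4:
        raise ValueError("need at least 4 samples in the group")
    if clr_matrix.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    x = clr_matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = list(clr_matrix.index[sd == 0])
        warnings.warn(
            f"excluding {len(bad)} taxa with constant CLR vectors (undefined correlation)",
            stacklevel=2,
        )
        clr_matrix = clr_matrix.loc[sd > 0]
        x = clr_matrix.to_numpy(dtype=float)
    taxa = list(clr_matrix.index)
    r = np.corrcoef(x)
    np.fill_diagonal(r, 0.0)
    ii, jj = np.where(np.triu(np.abs(r) >= threshold, k=1))

    g = nx.Graph(threshold=float(threshold))
    if group_salinity is not None:
        g.graph["group_salinity"] = float(group_salinity)
    if group_id is not None:
        g.graph["group_id"] = str(group_id)
    for i, j in zip(ii.tolist(), jj.tolist()):
        rij = float(r[i, j])
        g.add_edge(taxa[i], taxa[j], r=rij, sign=1 if rij > 0 else -1)
    return g


def connectedness(g: nx.Graph) -> float:
    """Krackhardt connectedness: the fraction of unordered node pairs joined
    by a path.  0 for a graph without links, 1 for a connected graph."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if n == 1:
        return 1.0
    reachable = sum(len(c) * (len(c) - 1) // 2 for c in nx.connected_components(g))
    return reachable / (n * (n - 1) // 2)


def powerlaw_fit(degree_sequence) -> float:
    """R-squared of an OLS fit of ln(frequency) on ln(degree) over the
    observed (nonzero) degrees.  Undefined (NaN) with fewer than 3 distinct
    degree values."""
    deg = np.asarray(list(degree_sequence), dtype=float)
    deg = deg[deg > 0]
    ks, freq = np.unique(deg, return_counts=True)
    if ks.size < 3:
        warnings.warn("fewer than 3 distinct degrees; power-law fit undefined", stacklevel=2)
        return float("nan")
    logf = np.log(freq.astype(float))
    if np.ptp(logf) == 0:
        return 0.0  # flat frequencies: no variance for the fit to explain
    fit = stats.linregress(np.log(ks), logf)
    return float(fit.rvalue) ** 2


@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_links: int
    avg_degree: float
    avg_clustering: float
    density: float
    connectedness: float
    modularity: float
    n_modules: int
    powerlaw_r_squared: float


def topology(g: nx.Graph) -> TopologyReport:
    """Summarise a network.  Modularity and module count come from greedy
    (CNM) modularity maximisation on the unweighted graph; for an edgeless
    graph modularity is undefined (NaN) and each node is its own module."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    m = g.number_of_edges()
    degrees = [d for _, d in g.degree()]
    avg_degree = 2.0 * m / n
    density = 0.0 if n < 2 else 2.0 * m / (n * (n - 1))
    avg_clustering = float(np.mean(list(nx.clustering(g).values())))
    if m == 0:
        modularity, n_modules = float("nan"), n
    else:
        communities = nx.algorithms.community.greedy_modularity_communities(g)
        modularity = float(nx.algorithms.community.modularity(g, communities))
        n_modules = len(communities)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plaw = powerlaw_fit(degrees)
    return TopologyReport(
        n_nodes=n,
        n_links=m,
        avg_degree=avg_degree,
        avg_clustering=avg_clustering,
        density=density,
        connectedness=connectedness(g),
        modularity=modularity,
        n_modules=n_modules,
        powerlaw_r_squared=plaw,
    )
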