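"""Network robustness under simulated species extinction.

Stability is probed by removing a random fraction of nodes and recomputing
two indices on the induced subgraph: the average degree and the natural
connectivity, the log mean exponential of the adjacency eigenvalues

    nc = ln( (1/N) sum_i exp(lambda_i) ),

a spectral measure of the redundancy of alternative paths that degrades
smoothly as a graph loses structure.  Survivors left isolated by a removal
stay in the node set for both indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.special import logsumexp

from .gradient import TrendResult, linear_trend


def natural_connectivity(g: nx.Graph) -> float:
    """Natural connectivity of the unsigned, unweighted adjacency matrix.
    Defined for any (possibly disconnected) non-empty graph; 0 for an
    edgeless graph."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        return 0.0
    a = nx.to_numpy_array(g, weight=None)
    lam = eigh(a, eigvals_only=True)
    return float(logsumexp(lam) - np.log(n))


def _avg_degree(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    return 0.0 if n == 0 else 2.0 * g.number_of_edges() / n


@dataclass
class RobustnessResult:
    """Replicate-level robustness measurements for one network."""

    records: pd.DataFrame  # columns: fraction, replicate, avg_degree, natural_connectivity
    n_replicates: int
    seed: int | None

    def summary(self) -> pd.DataFrame:
        return (
            self.records.groupby("fraction")[["avg_degree", "natural_connectivity"]]
            .agg(["mean", "std"])
            .reset_index()
        )

    def mean_at(self, fraction: float, metric: str) -> float:
        sel = self.records[np.isclose(self.records["fraction"], fraction)]
        if sel.empty:
            raise ValueError(f"fraction {fraction} not simulated")
        return float(sel[metric].mean())


def removal_simulation(
    g: nx.Graph,
    fractions,
    n_replicates: int = 100,
    seed: int | None = None,
) -> RobustnessResult:
    """Randomly remove round(p*N) nodes per replicate for each removal
    fraction p and record average degree and natural connectivity of the
    induced subgraph (isolated survivors retained)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    fractions = [float(p) for p in fractions]
    for p in fractions:
        if not 0.0 <= p < 1.0:
            raise ValueError(f"removal fraction {p} outside [0, 1)")
        if int(round(p * n)) >= n:
            raise ValueError(f"fraction {p} would remove all {n} nodes")
    rng = np.random.default_rng(seed)
    nodes = np.array(list(g.nodes()), dtype=object)
    rows = []
    for p in fractions:
        k = int(round(p * n))
        for rep in range(n_replicates):
            if k == 0:
                sub = g
            else:
                removed = rng.choice(n, size=k, replace=False)
                keep = np.ones(n, dtype=bool)
                keep[removed] = False
                sub = g.subgraph(nodes[keep])
            rows.append(
                {
                    "fraction": p,
                    "replicate": rep,
                    "avg_degree": _avg_degree(sub),
                    "natural_connectivity": natural_connectivity(sub),
                }
            )
    return RobustnessResult(records=pd.DataFrame(rows), n_replicates=n_replicates, seed=seed)


def stability_trend(
    results: list[RobustnessResult],
    salinities,
    fraction: float,
    metric: str = "natural_connectivity",
) -> TrendResult:
    """Linear trend of the per-network mean robustness index at a fixed
    removal fraction against the networks' group salinities."""
    salinities = list(salinities)
    if len(results) != len(salinities):
        raise ValueError("one salinity per network required")
    if len(results) < 3:
        raise ValueError("need at least 3 networks")
    y = [res.mean_at(fraction, metric) for res in results]
    return linear_trend(salinities, y)
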