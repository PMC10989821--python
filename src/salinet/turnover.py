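"""Turnover of network communities along the gradient.

A *network community* is the set of taxa (nodes) supporting one salinity
group's co-occurrence network — distinct from the intra-network modules.
Turnover is quantified by set overlap between communities, decomposed by
abundance class, and by Bray-Curtis compositional similarity regressed on
the salinity span between networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .gradient import TrendResult, linear_trend
from .prep import SalinityGroup, relative_abundance
from .simulate import CLASSES


@dataclass
class NetworkCommunity:
    network_id: str
    nodes: frozenset
    #: taxon -> abundance class for member taxa
    classes: dict
    #: mean relative abundance of member taxa (over the network's samples)
    abundance: pd.Series
    mean_salinity: float | None = None


def make_community(
    net: nx.Graph,
    table: pd.DataFrame,
    group: SalinityGroup,
    classes: pd.Series,
    network_id: str | None = None,
) -> NetworkCommunity:
    """Assemble the community record for one network: its node set, the
    abundance class of each member, and the members' mean relative
    abundance across the network's own sample group."""
    nodes = frozenset(net.nodes())
    missing = nodes - set(table.index)
    if missing:
        raise ValueError(f"nodes absent from the abundance table: {sorted(missing)[:5]} ...")
    ra = relative_abundance(table[list(group.sample_ids)])
    return NetworkCommunity(
        network_id=network_id or net.graph.get("group_id", group.group_id),
        nodes=nodes,
        classes={t: classes[t] for t in nodes},
        abundance=ra.loc[sorted(nodes)].mean(axis=1),
        mean_salinity=group.mean_salinity,
    )


def _class_proportions(taxa, classes: dict) -> dict | None:
    taxa = list(taxa)
    if not taxa:
        return None
    labels = pd.Series([classes[t] for t in taxa])
    return {c: float((labels == c).mean()) for c in CLASSES}


@dataclass
class OverlapResult:
    overlap: frozenset
    unique_to_first: frozenset
    unique_to_second: frozenset
    #: per-set abundance-class proportions; None for an empty set
    overlap_classes: dict | None
    unique_first_classes: dict | None
    unique_second_classes: dict | None


def community_overlap(c1: NetworkCommunity, c2: NetworkCommunity) -> OverlapResult:
    classes = {**c1.classes, **c2.classes}
    inter = c1.nodes & c2.nodes
    only1 = c1.nodes - c2.nodes
    only2 = c2.nodes - c1.nodes
    return OverlapResult(
        overlap=frozenset(inter),
        unique_to_first=frozenset(only1),
        unique_to_second=frozenset(only2),
        overlap_classes=_class_proportions(inter, classes),
        unique_first_classes=_class_proportions(only1, classes),
        unique_second_classes=_class_proportions(only2, classes),
    )


def community_similarity(
    c1: NetworkCommunity, c2: NetworkCommunity, mode: str = "abundance"
) -> float:
    """1 - Bray-Curtis distance between the two communities' composition
    vectors over the union of their nodes (non-members contribute 0).

    mode='abundance' uses the mean relative abundances; mode='presence'
    uses 0/1 membership.
    """
    union = sorted(c1.nodes | c2.nodes)
    if not union:
        raise ValueError("both communities are empty")
    if mode == "abundance":
        u = c1.abundance.reindex(union).fillna(0.0).to_numpy()
        v = c2.abundance.reindex(union).fillna(0.0).to_numpy()
    elif mode == "presence":
        u = np.array([1.0 if t in c1.nodes else 0.0 for t in union])
        v = np.array([1.0 if t in c2.nodes else 0.0 for t in union])
    else:
        raise ValueError("mode must be 'abundance' or 'presence'")
    denom = (u + v).sum()
    if denom == 0:
        raise ValueError("both composition vectors are all-zero")
    bc = np.abs(u - v).sum() / denom
    return float(1.0 - bc)


def turnover_trend(
    communities: list[NetworkCommunity],
    salinities=None,
    mode: str = "abundance",
) -> TrendResult:
    """Linear trend of pairwise community similarity against the absolute
    salinity span |delta mean salinity|, over all network pairs."""
    if len(communities) < 3:
        raise ValueError("need at least 3 networks")
    if salinities is None:
        salinities = [c.mean_salinity for c in communities]
    salinities = [float(s) for s in salinities]
    spans, sims = [], []
    for i in range(len(communities)):
        for j in range(i + 1, len(communities)):
            spans.append(abs(salinities[i] - salinities[j]))
            sims.append(community_similarity(communities[i], communities[j], mode=mode))
    return linear_trend(spans, sims)
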