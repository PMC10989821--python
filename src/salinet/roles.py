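"""Relative importance of the abundant and rare biospheres in the networks.

The core statistic is the *relative degree*: a node's degree divided by its
network's average degree, which makes node importance comparable between
networks of very different size and connectance.  Per network, the
abundant-minus-rare mean relative degree and Freeman's theta (an ordinal
effect size on the two classes' relative-degree distributions) summarise
the gap between the biospheres; their linear trends against salinity track
how stress reshapes that gap.  Levins' niche breadth quantifies why: taxa
occupying many samples evenly (large B) tolerate a wider stretch of the
gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .gradient import TrendResult, linear_trend
from .simulate import ABUNDANT, RARE


def relative_degree(
    net: nx.Graph, classes: pd.Series, network_id: str | None = None
) -> pd.DataFrame:
    """One record per node: degree, degree / network average degree, and
    abundance class.  The mean relative degree over a network's nodes is 1
    by construction."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    avg = 2.0 * net.number_of_edges() / n
    if avg == 0:
        raise ValueError("edgeless network: relative degree undefined")
    nid = network_id or net.graph.get("group_id", "")
    rows = [
        {
            "network_id": nid,
            "taxon": node,
            "degree": d,
            "relative_degree": d / avg,
            "abundance_class": classes.get(node, "unknown"),
        }
        for node, d in net.degree()
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClassGap:
    mean_abundant: float
    mean_rare: float
    difference: float
    defined: bool


def class_gap(records: pd.DataFrame) -> ClassGap:
    """Mean relative degree of abundant nodes minus that of rare nodes for
    one network.  Undefined (flagged, NaN) when either class is absent."""
    rd = records.set_index("abundance_class")["relative_degree"]
    ab = rd.loc[[ABUNDANT]] if ABUNDANT in rd.index else pd.Series(dtype=float)
    ra = rd.loc[[RARE]] if RARE in rd.index else pd.Series(dtype=float)
    if ab.empty or ra.empty:
        warnings.warn("a biosphere class is absent; class gap undefined", stacklevel=2)
        return ClassGap(
            mean_abundant=float(ab.mean()) if not ab.empty else float("nan"),
            mean_rare=float(ra.mean()) if not ra.empty else float("nan"),
            difference=float("nan"),
            defined=False,
        )
    return ClassGap(
        mean_abundant=float(ab.mean()),
        mean_rare=float(ra.mean()),
        difference=float(ab.mean() - ra.mean()),
        defined=True,
    )


def freeman_theta(group_a, group_b) -> float:
    """Freeman's theta over the n_a * n_b cross pairs:
    theta = |#(a > b) - #(a < b)| / (n_a * n_b); ties count toward neither.
    1 under complete separation, 0 when neither group dominates."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    gt = int((a[:, None] > b[None, :]).sum())
    lt = int((a[:, None] < b[None, :]).sum())
    return abs(gt - lt) / (a.size * b.size)


def role_trends(
    records_by_network: list[pd.DataFrame],
    salinities,
) -> dict[str, TrendResult]:
    """Four trends vs salinity: pooled node-level abundant and rare relative
    degrees (each node carries its network's mean salinity), the per-network
    abundant-minus-rare gap, and the per-network Freeman's theta.  Networks
    missing a class are skipped for the gap and theta fits."""
    salinities = [float(s) for s in salinities]
    if len(records_by_network) != len(salinities):
        raise ValueError("one salinity per network required")
    if len(records_by_network) < 3:
        raise ValueError("need at least 3 networks")

    ab_x, ab_y, ra_x, ra_y = [], [], [], []
    gap_x, gap_y, th_x, th_y = [], [], [], []
    for rec, s in zip(records_by_network, salinities):
        ab = rec.loc[rec["abundance_class"] == ABUNDANT, "relative_degree"]
        ra = rec.loc[rec["abundance_class"] == RARE, "relative_degree"]
        ab_x += [s] * len(ab)
        ab_y += ab.tolist()
        ra_x += [s] * len(ra)
        ra_y += ra.tolist()
        gap = class_gap(rec) if (len(ab) and len(ra)) else None
        if gap is not None and gap.defined:
            gap_x.append(s)
            gap_y.append(gap.difference)
            th_x.append(s)
            th_y.append(freeman_theta(ab, ra))
    return {
        "abundant_relative_degree": linear_trend(ab_x, ab_y),
        "rare_relative_degree": linear_trend(ra_x, ra_y),
        "class_gap": linear_trend(gap_x, gap_y),
        "freeman_theta": linear_trend(th_x, th_y),
    }


def levins_breadth(table: pd.DataFrame, classes: pd.Series | None = None) -> pd.DataFrame:
    """Levins' niche breadth per taxon: B = 1 / sum_j p_ij^2 where p_ij is
    sample j's share of taxon i's total.  B ranges from 1 (single-sample
    occupancy) to the number of samples (uniform occupancy); the
    standardised breadth B_A = (B - 1) / (n_samples - 1) rescales to [0, 1].
    All-zero taxa are excluded with a warning."""
    totals = table.sum(axis=1)
    if (totals == 0).any():
        warnings.warn(
            f"excluding {int((totals == 0).sum())} all-zero taxa from niche breadth",
            stacklevel=2,
        )
        table = table.loc[totals > 0]
        totals = totals[totals > 0]
    n = table.shape[1]
    p = table.div(totals, axis=0).to_numpy(dtype=float)
    b = 1.0 / (p**2).sum(axis=1)
    out = pd.DataFrame(
        {
            "levins_B": b,
            "standardized_B_A": (b - 1.0) / (n - 1.0) if n > 1 else np.zeros_like(b),
        },
        index=table.index,
    )
    if classes is not None:
        out["abundance_class"] = classes.reindex(out.index)
    return out


def breadth_comparison(breadth: pd.DataFrame) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test comparing Levins'
    B between abundant and rare taxa.  Returns (statistic, p_value)."""
    if "abundance_class" not in breadth.columns:
        raise ValueError("breadth table lacks an abundance_class column")
    a = breadth.loc[breadth["abundance_class"] == ABUNDANT, "levins_B"]
    r = breadth.loc[breadth["abundance_class"] == RARE, "levins_B"]
    if a.empty or r.empty:
        raise ValueError("both abundant and rare classes must be represented")
    method = "exact" if min(len(a), len(r)) < 8 else "auto"
    res = stats.mannwhitneyu(a, r, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
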