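"""Readers, writers and pipeline configuration.

Canonical on-disk formats are plain text: abundance tables as TSV with
taxa as rows (first column taxon id, header row of sample ids), sample
metadata as TSV with a ``salinity`` column, networks as GraphML or an
edge-list TSV, and configuration as YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml


def read_abundance_tsv(path) -> pd.DataFrame:
    """Read and validate a taxon x sample count table."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = next(s for s in samples if samples.count(s) > 1)
        raise ValueError(f"{path}: duplicate sample id {dup!r} in header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty abundance table")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        line = int(np.where(df.index == dup)[0][-1]) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: duplicate taxon id {dup!r} (line {line})")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r} in header")
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or missing entries")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric counts")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(f"{path}: negative count at taxon {df.index[i]!r}, sample {df.columns[j]!r}")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{path}: non-integer counts")
    return df.astype(np.int64)


def write_abundance_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata_tsv(path, salinity_col: str = "salinity") -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if salinity_col not in meta.columns:
        raise ValueError(f"{path}: missing required column {salinity_col!r}")
    if meta.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return meta


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy_tsv(path) -> pd.Series:
    """Taxon -> group label mapping (first column taxon id, second the
    label used for feature aggregation, e.g. class)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError("taxonomy table needs at least one label column")
    return df.iloc[:, 0]


# --- networks ---------------------------------------------------------------

def write_network(net: nx.Graph, path, fmt: str = "graphml") -> None:
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            for key in ("group_id", "group_salinity", "threshold"):
                if key in net.graph:
                    fh.write(f"# {key}={net.graph[key]}\n")
            fh.write("source\ttarget\tr\tsign\n")
            for u, v, d in sorted(net.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['r']:.17g}\t{d['sign']}\n")
    else:
        raise ValueError("fmt must be 'graphml' or 'tsv'")


def read_network(path, fmt: str = "graphml") -> nx.Graph:
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        for k in ("group_salinity", "threshold"):
            if k in g.graph:
                g.graph[k] = float(g.graph[k])
        for _, _, d in g.edges(data=True):
            d["r"] = float(d["r"])
            d["sign"] = int(d["sign"])
        return g
    if fmt == "tsv":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, val = line[1:].strip().split("=", 1)
                    g.graph[key] = val if key == "group_id" else float(val)
                    continue
                if line.startswith("source\t") or not line:
                    continue
                u, v, r, sign = line.split("\t")
                g.add_edge(u, v, r=float(r), sign=int(sign))
        return g
    raise ValueError("fmt must be 'graphml' or 'tsv'")


# --- configuration ----------------------------------------------------------

@dataclass
class PipelineConfig:
    counts_path: str = ""
    metadata_path: str = ""
    taxonomy_path: str | None = None
    outdir: str = "salinet_out"
    rarefaction_depth: int = 51_323
    n_groups: int = 6
    group_remainder: str = "error"
    prevalence_fraction: float = 1.0
    correlation_threshold: float = 0.96
    pseudocount: float = 1.0
    abundant_min: float = 1e-3
    rare_max: float = 1e-4
    removal_fractions: list[float] = field(default_factory=lambda: [0.1, 0.3, 0.5])
    n_removal_replicates: int = 100
    mantel_permutations: int = 999
    rf_iterations: int = 1000
    rf_trees: int = 500
    cv_folds: int = 10
    cv_repeats: int = 5
    rf_grid_max: int = 20
    similarity_mode: str = "abundance"
    seed: int = 0

    def validate(self) -> None:
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if not 0.0 < self.correlation_threshold <= 1.0:
            raise ValueError(f"correlation_threshold {self.correlation_threshold} outside (0, 1]")
        if not 0.0 < self.prevalence_fraction <= 1.0:
            raise ValueError("prevalence_fraction outside (0, 1]")
        if not self.abundant_min > self.rare_max > 0:
            raise ValueError("abundance thresholds must satisfy abundant_min > rare_max > 0")
        for p in self.removal_fractions:
            if not 0.0 <= p < 1.0:
                raise ValueError(f"removal fraction {p} outside [0, 1)")
        if self.n_groups < 1 or self.n_removal_replicates < 1:
            raise ValueError("counts must be >= 1")
        if self.group_remainder not in ("error", "trim"):
            raise ValueError("group_remainder must be 'error' or 'trim'")
        if self.similarity_mode not in ("abundance", "presence"):
            raise ValueError("similarity_mode must be 'abundance' or 'presence'")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def dump_json(obj, path) -> None:
    """Deterministic JSON writer (sorted keys, no timestamps)."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
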