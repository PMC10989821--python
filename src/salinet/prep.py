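"""Community preparation: rarefaction, biosphere classification,
salinity-ordered grouping, prevalence filtering, and the centred log-ratio
transform.

The biosphere classification follows the common mean-relative-abundance
convention: taxa averaging above 0.1% are the abundant biosphere, below
0.01% the rare biosphere, anything in between (inclusive of the boundaries)
the intermediate biosphere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ABUNDANT, ABUNDANT_MIN, INTERMEDIATE, RARE, RARE_MAX


@dataclass(frozen=True)
class SalinityGroup:
    """A block of consecutive samples along the sorted salinity axis."""

    group_id: str
    sample_ids: tuple[str, ...]
    mean_salinity: float


@dataclass
class RarefactionResult:
    table: pd.DataFrame
    depth: int
    dropped: list[str]


def _validate_table(table: pd.DataFrame) -> None:
    if table.empty:
        raise ValueError("abundance table is empty")
    if (table.to_numpy() < 0).any():
        raise ValueError("abundance table contains negative counts")
    if table.index.duplicated().any():
        raise ValueError("duplicate taxon ids")
    if table.columns.duplicated().any():
        raise ValueError("duplicate sample ids")


def rarefy(table: pd.DataFrame, depth: int, seed: int | None = None) -> RarefactionResult:
    """Subsample each sample (column) to exactly ``depth`` reads without
    replacement (multivariate hypergeometric draw).  Samples with fewer than
    ``depth`` total reads are dropped and listed in the result."""
    _validate_table(table)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sum(axis=0)
    kept = [s for s in table.columns if totals[s] >= depth]
    dropped = [s for s in table.columns if totals[s] < depth]
    if not kept:
        raise ValueError(
            f"all {len(dropped)} samples have fewer than {depth} reads; nothing to rarefy"
        )
    out = np.empty((table.shape[0], len(kept)), dtype=np.int64)
    counts = table[kept].to_numpy(dtype=np.int64)
    for j in range(len(kept)):
        col = counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    rarefied = pd.DataFrame(out, index=table.index, columns=kept)
    return RarefactionResult(table=rarefied, depth=depth, dropped=dropped)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    totals = table.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total reads")
    return table / totals


def classify_abundance(
    table: pd.DataFrame,
    abundant_min: float = ABUNDANT_MIN,
    rare_max: float = RARE_MAX,
) -> pd.Series:
    """Biosphere class per taxon from its mean relative abundance across all
    samples.  Strict inequalities: boundary values fall in the intermediate
    class."""
    _validate_table(table)
    if not abundant_min > rare_max > 0:
        raise ValueError("thresholds must satisfy abundant_min > rare_max > 0")
    mean_ra = relative_abundance(table).mean(axis=1)
    out = pd.Series(INTERMEDIATE, index=table.index, name="abundance_class", dtype=object)
    out[mean_ra > abundant_min] = ABUNDANT
    out[mean_ra < rare_max] = RARE
    return out


def assign_salinity_groups(
    meta: pd.DataFrame,
    n_groups: int,
    salinity_col: str = "salinity",
    remainder: str = "error",
) -> list[SalinityGroup]:
    """Sort samples by salinity (ties broken by sample id, lexicographic)
    and chunk them into ``n_groups`` consecutive equal-size blocks.

    ``remainder='trim'`` drops the highest-salinity leftover samples when
    the count is not divisible; the default is to fail.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    order = meta[[salinity_col]].copy()
    order["__id"] = order.index.astype(str)
    order = order.sort_values([salinity_col, "__id"], kind="mergesort")
    n = len(order)
    size, extra = divmod(n, n_groups)
    if extra:
        if remainder == "trim":
            order = order.iloc[: size * n_groups]
        else:
            raise ValueError(
                f"{n} samples are not divisible into {n_groups} equal groups "
                "(pass remainder='trim' to drop the highest-salinity leftovers)"
            )
    if size == 0:
        raise ValueError("more groups than samples")
    groups = []
    for g in range(n_groups):
        block = order.iloc[g * size : (g + 1) * size]
        groups.append(
            SalinityGroup(
                group_id=f"n{g + 1}",
                sample_ids=tuple(block.index),
                mean_salinity=float(block[salinity_col].mean()),
            )
        )
    return groups


def prevalence_filter(
    table: pd.DataFrame,
    sample_ids,
    min_prevalence_fraction: float = 1.0,
) -> pd.DataFrame:
    """Restrict to the given samples and keep taxa with nonzero counts in at
    least ceil(fraction * n_samples) of them."""
    if not 0.0 < min_prevalence_fraction <= 1.0:
        raise ValueError("min_prevalence_fraction must lie in (0, 1]")
    sample_ids = list(sample_ids)
    sub = table[sample_ids]
    need = math.ceil(min_prevalence_fraction * len(sample_ids))
    keep = (sub > 0).sum(axis=1) >= need
    return sub.loc[keep]


def clr_transform(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform, per sample (column):
    x -> ln(x + pseudocount) - mean_taxa ln(x + pseudocount).

    Each transformed sample sums to zero.  A positive pseudocount is
    required whenever zeros are present.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if pseudocount == 0 and (x == 0).any():
        raise ValueError("zeros present: a positive pseudocount is required")
    logx = np.log(x + pseudocount)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=table.index, columns=table.columns)


def drop_all_zero_taxa(table: pd.DataFrame, warn: bool = True) -> pd.DataFrame:
    zero = table.sum(axis=1) == 0
    if zero.any() and warn:
        warnings.warn(f"dropping {int(zero.sum())} all-zero taxa", stacklevel=2)
    return table.loc[~zero]
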