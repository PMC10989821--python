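"""Synthetic salinity-gradient communities.

Generates taxon-by-sample count tables with the statistical structure the
downstream analysis assumes: a hyperdominant abundance distribution (a few
taxa holding most reads), Gaussian niche responses along a salinity gradient
(producing diversity decline and taxonomic turnover), broader niches for
abundant than for rare taxa, and module-structured inter-taxon associations
whose strength changes linearly with salinity.

The mechanism, per sample j at salinity s_j, for taxon i in module m(i):

    eta_ij = ln(base_i) - (s_j - mu_i)^2 / (2 sigma_i^2)
             + lambda_i(s_j) * f_{m(i), j} + eps_ij
    p_.j   = softmax(eta_.j)          counts_.j ~ Multinomial(depth, p_.j)

where f_{m,j} ~ N(0,1) is a latent factor shared by all members of module m
in sample j (inducing positive within-module correlation on the log scale),
lambda_i(s) = max(0, a_c + b_c (s - s_min)) is a per-abundance-class linear
loading in salinity, and eps is idiosyncratic lognormal noise.  Because the
latent factor enters *before* the softmax re-normalisation, module-mates end
up correlated after the centred log-ratio transform, and a negative loading
slope erodes those correlations toward the saline end of the gradient.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

ABUNDANT = "abundant"
INTERMEDIATE = "intermediate"
RARE = "rare"
CLASSES = (ABUNDANT, INTERMEDIATE, RARE)

#: mean relative abundance thresholds defining the biospheres
ABUNDANT_MIN = 1e-3
RARE_MAX = 1e-4


@dataclass
class GradientDesign:
    """Parameters of a simulated freshwater-to-seawater survey.

    Defaults mirror the emulated survey: three transects of sixteen
    consecutive sites (48 samples), salinity spanning roughly 0.8-21 g/L,
    and samples sequenced to a common depth of 51,323 reads.  The dominant
    6.5% of taxa are calibrated to carry ~70% of the reads.
    """

    n_transects: int = 3
    sites_per_transect: int = 16
    salinity_range: tuple[float, float] = (0.8, 21.0)
    n_taxa: int = 2000
    #: (fraction of taxa that are dominant, read share they carry)
    hyperdominance: tuple[float, float] = (0.065, 0.70)
    #: Gaussian niche tolerance sigma (g/L) per abundance class
    niche_width_by_class: Mapping[str, float] = field(
        default_factory=lambda: {ABUNDANT: 12.0, INTERMEDIATE: 6.0, RARE: 3.0}
    )
    n_modules: int = 6
    #: latent-factor loading at the fresh end of the gradient
    base_loading: float = 1.2
    #: slope of the loading vs salinity (per g/L); negative = decaying
    association_strength_decay: float = -0.05
    #: optional per-class (intercept, slope) overriding the two fields above
    class_loading: Optional[Mapping[str, tuple[float, float]]] = None
    #: fraction of taxa holding a secondary module membership; bridge taxa
    #: couple module pairs with cross-correlations that survive the CLR
    #: (a factor shared by *all* taxa would be a common mode that the
    #: closure and the CLR cancel)
    bridge_fraction: float = 0.15
    #: loading weight of the secondary membership relative to the primary
    bridge_weight: float = 0.6
    #: linear change of the bridge weight per g/L above the fresh end
    #: (negative values erode inter-module bridging seaward)
    bridge_weight_slope: float = 0.0
    #: how secondary memberships are placed: 'random' (any other module),
    #: 'chain' (the next module, so modules form a line whose links break
    #: one by one as bridges die, letting connectedness degrade through
    #: intermediate values), or 'mixed' (half chain, half random)
    bridge_topology: str = "mixed"
    #: decay slope for the diffuse (random-topology) bridges; None means
    #: use bridge_weight_slope for both populations
    diffuse_bridge_slope: float | None = None
    #: hierarchical module structure: modules are grouped into this many
    #: supergroups whose shared factor dominates at the fresh end and
    #: splits into per-module factors seaward (module differentiation
    #: under stress); 0 disables the hierarchy
    n_supergroups: int = 0
    #: fraction of factor variance carried by the supergroup at the fresh end
    supergroup_mix_start: float = 0.85
    #: change of that fraction per g/L (negative = modules split seaward)
    supergroup_mix_slope: float = -0.05
    #: relative jitter of the per-taxon loading and bridge decay slopes
    #: (taxon i's slope is scaled by 1 + jitter*U(-1,1)); staggers the
    #: salinity at which taxa drop out of the association structure so the
    #: network erodes gradually instead of through sharp percolation steps
    loading_slope_jitter: float = 0.0
    #: if > 0, standardise each module factor (mean 0, variance 1) within
    #: this many consecutive blocks of the salinity-sorted sample order — a
    #: variance-control device for benchmark designs that keeps the realised
    #: association strength of a module from fluctuating between blocks
    factor_standardize_blocks: int = 0
    #: idiosyncratic lognormal noise sd on log-abundance
    taxon_noise_sd: float = 0.4
    #: Beta(1, skew) placement of niche optima; >1 skews optima fresh-ward
    niche_skew: float = 1.8
    #: lognormal sd of base abundances within the dominant / tail blocks
    dominant_sigma: float = 0.6
    tail_sigma: float = 0.7
    salinity_jitter: float = 0.15
    sequencing_depth: int = 51_323
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.salinity_range
        if not lo < hi:
            raise ValueError(f"salinity_range must satisfy min < max, got {self.salinity_range}")
        frac, share = self.hyperdominance
        if not 0.0 < frac < 1.0:
            raise ValueError(f"hyperdominance fraction must lie in (0,1), got {frac}")
        if not 0.0 < share < 1.0:
            raise ValueError(f"hyperdominance share must lie in (0,1), got {share}")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        for name in ("n_transects", "sites_per_transect", "n_taxa", "n_modules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_taxa < self.n_modules:
            raise ValueError(
                f"degenerate design: n_taxa ({self.n_taxa}) < n_modules ({self.n_modules}); "
                "every module needs at least one member taxon"
            )
        missing = [c for c in CLASSES if c not in self.niche_width_by_class]
        if missing:
            raise ValueError(f"niche_width_by_class missing classes: {missing}")
        if self.taxon_noise_sd < 0 or self.salinity_jitter < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0.0 <= self.bridge_fraction <= 1.0:
            raise ValueError("bridge_fraction must lie in [0, 1]")
        if self.n_supergroups < 0 or self.n_supergroups > self.n_modules:
            raise ValueError("n_supergroups must lie in [0, n_modules]")
        if not 0.0 <= self.supergroup_mix_start <= 1.0:
            raise ValueError("supergroup_mix_start must lie in [0, 1]")
        if self.bridge_weight < 0:
            raise ValueError("bridge_weight must be non-negative")
        if self.bridge_topology not in ("random", "chain", "mixed"):
            raise ValueError("bridge_topology must be 'random', 'chain' or 'mixed'")

    def replace(self, **kw) -> "GradientDesign":
        return dataclasses.replace(self, **kw)


def _softmax_columns(eta: np.ndarray) -> np.ndarray:
    z = eta - eta.max(axis=0, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=0, keepdims=True)
    return p


def _calibrate_dominant_share(
    log_base: np.ndarray, niche: np.ndarray, dominant: np.ndarray, target: float, n_iter: int = 8
) -> np.ndarray:
    """Shift the dominant block's log base abundance so its expected read
    share, averaged over samples and including niche modulation, hits the
    target.  Fixed-point iteration on the logit of the share."""
    log_base = log_base.copy()
    for _ in range(n_iter):
        p = _softmax_columns(log_base[:, None] + niche)
        share = p[dominant].sum(axis=0).mean()
        share = min(max(share, 1e-12), 1 - 1e-12)
        log_base[dominant] += np.log(target / (1 - target)) - np.log(share / (1 - share))
    return log_base


def simulate_gradient(
    design: GradientDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a gradient survey.

    Returns
    -------
    table : DataFrame
        Integer counts, taxa (rows) by samples (columns); every column sums
        exactly to ``design.sequencing_depth``.
    meta : DataFrame
        Per-sample metadata indexed by sample id: transect, site, salinity
        (g/L), latitude/longitude (decimal degrees) and correlated
        physicochemical covariates (pH, DOC, NO3, NH4).
    ground_truth : dict
        Per-taxon niche optimum ``mu``, tolerance ``sigma``, design
        abundance class, module memberships and loading parameters, plus
        the per-sample salinity.
    """
    design.validate()
    lo, hi = design.salinity_range
    n_samples = design.n_transects * design.sites_per_transect
    n_taxa = design.n_taxa

    root = np.random.SeedSequence(design.seed)
    # documented stream split: one child stream per stochastic ingredient
    rng_env, rng_base, rng_niche, rng_factor, rng_counts = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    # --- sample frame: transects of consecutive sites, salinity monotone
    # along each transect up to a small jitter -------------------------------
    sample_ids, transects, sites, salinity, lat, lon = [], [], [], [], [], []
    for t in range(design.n_transects):
        grid = np.linspace(lo, hi, design.sites_per_transect)
        jit = rng_env.normal(0.0, design.salinity_jitter, design.sites_per_transect)
        sal = np.clip(grid + jit, lo, hi)
        for s_idx in range(design.sites_per_transect):
            sample_ids.append(f"T{t + 1}S{s_idx + 1:02d}")
            transects.append(t + 1)
            sites.append(s_idx + 1)
            salinity.append(sal[s_idx])
            # sites laid out every ~1.1 km along a south-north line per transect
            lat.append(36.0 + 0.01 * s_idx)
            lon.append(120.0 + 0.8 * t)
    salinity = np.asarray(salinity)

    meta = pd.DataFrame(
        {
            "transect": transects,
            "site": sites,
            "salinity": salinity,
            "latitude": lat,
            "longitude": lon,
            # nutrient-like covariates declining seaward, pH mildly rising
            "pH": 7.6 + 0.02 * salinity + rng_env.normal(0, 0.05, n_samples),
            "DOC": 8.0 - 0.25 * salinity + rng_env.normal(0, 0.4, n_samples),
            "NO3": 2.0 - 0.07 * salinity + rng_env.normal(0, 0.12, n_samples),
            "NH4": 1.0 - 0.03 * salinity + rng_env.normal(0, 0.08, n_samples),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- base abundances: dominant block + lognormal tail -------------------
    frac_dom, share_dom = design.hyperdominance
    k = max(1, int(round(frac_dom * n_taxa)))
    dominant = np.zeros(n_taxa, dtype=bool)
    dominant[:k] = True
    w = np.empty(n_taxa)
    w_dom = np.exp(rng_base.normal(0.0, design.dominant_sigma, k))
    w_tail = np.exp(rng_base.normal(0.0, design.tail_sigma, n_taxa - k))
    w[:k] = share_dom * w_dom / w_dom.sum()
    w[k:] = (1 - share_dom) * w_tail / w_tail.sum()
    log_base = np.log(w)

    # design class from the base composition (the generator's ground truth;
    # downstream classification re-derives classes from realised counts)
    klass = np.where(w > ABUNDANT_MIN, ABUNDANT, np.where(w < RARE_MAX, RARE, INTERMEDIATE))

    # --- Gaussian niches -----------------------------------------------------
    mu = lo + (hi - lo) * rng_niche.beta(1.0, design.niche_skew, n_taxa)
    sigma = np.array([design.niche_width_by_class[c] for c in klass])
    niche = -((salinity[None, :] - mu[:, None]) ** 2) / (2.0 * sigma[:, None] ** 2)

    log_base = _calibrate_dominant_share(log_base, niche, dominant, share_dom)

    # --- module structure and salinity-dependent loadings --------------------
    # round-robin over a shuffled taxon order balances classes across modules
    order = rng_factor.permutation(n_taxa)
    module = np.empty(n_taxa, dtype=int)
    module[order] = np.arange(n_taxa) % design.n_modules

    loading_params = {c: (design.base_loading, design.association_strength_decay) for c in CLASSES}
    if design.class_loading is not None:
        loading_params.update({c: tuple(v) for c, v in design.class_loading.items()})
    a = np.array([loading_params[c][0] for c in klass])
    b = np.array([loading_params[c][1] for c in klass])
    jit = 1.0 + design.loading_slope_jitter * rng_factor.uniform(-1.0, 1.0, n_taxa)
    jit_a = 1.0 + 0.5 * design.loading_slope_jitter * rng_factor.uniform(-1.0, 1.0, n_taxa)
    lam = np.clip(
        (a * jit_a)[:, None] + (b * jit)[:, None] * (salinity[None, :] - lo), 0.0, None
    )

    factors = rng_factor.normal(0.0, 1.0, (design.n_modules, n_samples))
    super_factors = rng_factor.normal(
        0.0, 1.0, (max(design.n_supergroups, 1), n_samples)
    )

    def _block_standardize(f: np.ndarray) -> np.ndarray:
        k_blocks = design.factor_standardize_blocks
        if k_blocks <= 0:
            return f
        order = np.argsort(salinity, kind="stable")
        size = n_samples // k_blocks
        f = f.copy()
        for blk in range(k_blocks):
            idx = order[blk * size : (blk + 1) * size if blk < k_blocks - 1 else n_samples]
            block = f[:, idx]
            f[:, idx] = (block - block.mean(axis=1, keepdims=True)) / block.std(
                axis=1, keepdims=True
            )
        return f

    factors = _block_standardize(factors)
    if design.n_supergroups > 0:
        super_factors = _block_standardize(super_factors)
        group_of = np.arange(design.n_modules) % design.n_supergroups
        mix_jit = 1.0 + 0.5 * design.loading_slope_jitter * rng_factor.uniform(
            -1.0, 1.0, design.n_modules
        )
        h = np.clip(
            design.supergroup_mix_start
            + design.supergroup_mix_slope * mix_jit[:, None] * (salinity[None, :] - lo),
            0.0,
            1.0,
        )
        factors = np.sqrt(1.0 - h) * factors + np.sqrt(h) * super_factors[group_of, :]
    # secondary memberships for bridge taxa (unit-variance combination)
    w = np.zeros(n_taxa)
    module2 = module.copy()
    sign2 = np.ones(n_taxa)
    is_diffuse = np.zeros(n_taxa, dtype=bool)
    diffuse_dir = np.zeros((n_taxa, design.n_modules))
    if design.n_modules > 1 and design.bridge_fraction > 0 and design.bridge_weight > 0:
        is_bridge = rng_factor.random(n_taxa) < design.bridge_fraction
        w[is_bridge] = design.bridge_weight
        # chain bridges couple module m to m+1 (a line of modules whose
        # links break one by one as bridges fade); diffuse bridges blur a
        # taxon's loading across *all* modules through a continuous random
        # direction, so the fresh-end community structure is genuinely
        # fuzzy rather than a collection of micro-cliques
        if design.bridge_topology == "chain":
            is_chain_taxon = np.ones(n_taxa, dtype=bool)
        elif design.bridge_topology == "random":
            is_chain_taxon = np.zeros(n_taxa, dtype=bool)
        else:  # mixed
            is_chain_taxon = rng_factor.random(n_taxa) < 0.5
        module2 = np.where(is_bridge & is_chain_taxon, (module + 1) % design.n_modules, module)
        sign2 = np.ones(n_taxa)
        diffuse_dir = rng_factor.normal(0.0, 1.0, (n_taxa, design.n_modules))
        diffuse_dir /= np.linalg.norm(diffuse_dir, axis=1, keepdims=True)
        is_diffuse = is_bridge & ~is_chain_taxon
    eps = rng_factor.normal(0.0, design.taxon_noise_sd, (n_taxa, n_samples))

    diffuse_slope = (
        design.bridge_weight_slope
        if design.diffuse_bridge_slope is None
        else design.diffuse_bridge_slope
    )
    slope_b = np.where(is_diffuse, diffuse_slope, design.bridge_weight_slope)
    # chain bridges share a per-module decay jitter so each inter-module
    # link dies at one (staggered) salinity instead of trailing off with
    # its slowest member taxon
    link_jit = 1.0 + design.loading_slope_jitter * rng_factor.uniform(
        -1.0, 1.0, design.n_modules
    )
    jit_b = np.where(is_diffuse, jit, link_jit[module])
    w_s = np.clip(
        w[:, None] + np.where(w[:, None] > 0, (slope_b * jit_b)[:, None], 0.0)
        * (salinity[None, :] - lo),
        0.0,
        None,
    )
    secondary = np.where(
        is_diffuse[:, None], diffuse_dir @ factors, sign2[:, None] * factors[module2, :]
    )
    # normalise by the fresh-end weight so a dying bridge removes shared
    # variance instead of re-concentrating it on the primary module
    latent = (factors[module, :] + w_s * secondary) / np.sqrt(1.0 + w[:, None] ** 2)
    eta = log_base[:, None] + niche + lam * latent + eps
    p = _softmax_columns(eta)

    counts = np.empty((n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = rng_counts.multinomial(design.sequencing_depth, p[:, j])

    taxon_ids = [f"taxon{i:04d}" for i in range(n_taxa)]
    table = pd.DataFrame(counts, index=pd.Index(taxon_ids, name="taxon_id"), columns=meta.index)

    ground_truth = {
        "mu": dict(zip(taxon_ids, mu.tolist())),
        "sigma": dict(zip(taxon_ids, sigma.tolist())),
        "abundance_class": dict(zip(taxon_ids, klass.tolist())),
        "module": dict(zip(taxon_ids, module.tolist())),
        "secondary_module": dict(zip(taxon_ids, module2.tolist())),
        "expected_mean_relative_abundance": dict(
            zip(taxon_ids, _softmax_columns(log_base[:, None] + niche).mean(axis=1).tolist())
        ),
        "loading_intercept": dict(zip(taxon_ids, a.tolist())),
        "loading_slope": dict(zip(taxon_ids, b.tolist())),
        "salinity": dict(zip(sample_ids, salinity.tolist())),
    }
    return table, meta, ground_truth


#: uniform |r| threshold and grouping used by the two benchmark designs
#: below (16-sample groups keep the Pearson estimate stable at desk scale)
BENCHMARK_THRESHOLD = 0.78
BENCHMARK_N_GROUPS = 6


def association_decay_design(**overrides) -> GradientDesign:
    """The planted-decay benchmark: a six-transect survey whose module
    structure erodes seaward on every axis — per-taxon loadings decay,
    inter-module chain links break one by one, and three merged supergroups
    split into their nine constituent modules (niche differentiation under
    stress).  Analysed with :data:`BENCHMARK_THRESHOLD` and
    :data:`BENCHMARK_N_GROUPS` groups, the resulting networks lose nodes,
    links, degree, density and connectedness and gain modularity along the
    gradient."""
    base = dict(
        n_taxa=600,
        n_transects=6,
        n_modules=9,
        n_supergroups=3,
        supergroup_mix_start=0.9,
        supergroup_mix_slope=-0.03,
        base_loading=0.64,
        taxon_noise_sd=0.25,
        association_strength_decay=-0.02,
        bridge_fraction=0.4,
        bridge_weight=1.0,
        bridge_weight_slope=-0.05,
        loading_slope_jitter=0.5,
        bridge_topology="chain",
        sequencing_depth=150_000,
        factor_standardize_blocks=6,
        niche_width_by_class={ABUNDANT: 12.0, INTERMEDIATE: 9.0, RARE: 3.0},
        niche_skew=1.4,
    )
    base.update(overrides)
    return GradientDesign(**base)


def hub_erosion_design(**overrides) -> GradientDesign:
    """The hub-erosion benchmark: abundant taxa lose association strength
    seaward while rare taxa gain some, without the rare class overtaking
    the abundant class.  Niches are broad and optima unskewed so the class
    composition of the networks stays comparable along the gradient; what
    changes is who holds the links.  Class loadings sit below the edge
    saturation point so relative-degree contrasts stay visible."""
    base = dict(
        n_taxa=600,
        n_transects=6,
        n_modules=9,
        base_loading=0.64,
        taxon_noise_sd=0.25,
        class_loading={
            ABUNDANT: (0.5, -0.016),
            INTERMEDIATE: (0.35, -0.002),
            RARE: (0.25, 0.006),
        },
        bridge_fraction=0.4,
        bridge_weight=1.0,
        bridge_weight_slope=-0.05,
        loading_slope_jitter=0.5,
        bridge_topology="chain",
        sequencing_depth=150_000,
        factor_standardize_blocks=6,
        tail_sigma=1.2,
        niche_width_by_class={ABUNDANT: 30.0, INTERMEDIATE: 30.0, RARE: 30.0},
        niche_skew=1.0,
    )
    base.update(overrides)
    return GradientDesign(**base)
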