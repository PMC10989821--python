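"""End-to-end pipeline driver.

Runs preparation -> gradient statistics -> biomarkers -> networks ->
stability -> turnover -> biosphere roles on an abundance table plus sample
metadata, writing per-stage CSV/JSON reports and a provenance block into
the configured output directory.  Stages can be run individually; later
stages recompute the (cheap) preparation they depend on.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import __version__
from .biomarkers import SalinityBiomarkerSelector, aggregate_taxonomy
from .gradient import (
    alpha_diversity,
    bray_curtis_matrix,
    geo_env_correlation,
    linear_trend,
    mantel_test,
)
from .io import (
    PipelineConfig,
    dump_json,
    read_abundance_tsv,
    read_metadata_tsv,
    read_taxonomy_tsv,
    write_network,
)
from .network import build_network, topology
from .prep import (
    assign_salinity_groups,
    classify_abundance,
    clr_transform,
    prevalence_filter,
    rarefy,
    relative_abundance,
)
from .roles import breadth_comparison, levins_breadth, relative_degree, role_trends
from .stability import removal_simulation, stability_trend
from .turnover import community_overlap, community_similarity, make_community, turnover_trend

ALL_STAGES = ("prep", "gradient", "biomarkers", "networks", "stability", "turnover", "roles")

ENV_COLUMNS_EXCLUDED = {"transect", "site", "latitude", "longitude"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _trend_dict(t) -> dict:
    return dataclasses.asdict(t)


class Pipeline:
    """Stateful driver: ``run(stages)`` executes the requested stages in
    order and returns the report dictionary that was written to disk."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.outdir = Path(config.outdir)
        self._prepped = False

    # -- shared preparation --------------------------------------------------
    def _prepare(self):
        if self._prepped:
            return
        cfg = self.config
        table = read_abundance_tsv(cfg.counts_path)
        meta = read_metadata_tsv(cfg.metadata_path)
        missing = set(table.columns) - set(meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        rar = rarefy(table, cfg.rarefaction_depth, seed=cfg.seed)
        self.rarefied = rar.table
        self.dropped_samples = rar.dropped
        self.meta = meta.loc[self.rarefied.columns]
        self.classes = classify_abundance(
            self.rarefied, abundant_min=cfg.abundant_min, rare_max=cfg.rare_max
        )
        self.groups = assign_salinity_groups(
            self.meta, cfg.n_groups, remainder=cfg.group_remainder
        )
        self._prepped = True

    def _networks(self):
        if hasattr(self, "nets"):
            return
        cfg = self.config
        self.nets, self.net_groups, self.topologies = [], [], []
        for grp in self.groups:
            sub = prevalence_filter(
                self.rarefied, grp.sample_ids, cfg.prevalence_fraction
            )
            if sub.shape[0] < 2:
                warnings.warn(f"group {grp.group_id}: fewer than 2 prevalent taxa; skipped")
                continue
            pseudo = cfg.pseudocount if (sub.to_numpy() == 0).any() else 0.0
            clr = clr_transform(sub, pseudocount=pseudo)
            net = build_network(
                clr,
                cfg.correlation_threshold,
                group_salinity=grp.mean_salinity,
                group_id=grp.group_id,
            )
            if net.number_of_edges() == 0:
                warnings.warn(f"group {grp.group_id}: no correlations pass the threshold; skipped")
                continue
            self.nets.append(net)
            self.net_groups.append(grp)
            self.topologies.append(topology(net))

    # -- stages ---------------------------------------------------------------
    def stage_prep(self) -> dict:
        cfg = self.config
        out = self.outdir / "prep"
        out.mkdir(parents=True, exist_ok=True)
        self.classes.to_frame().to_csv(out / "abundance_classes.csv")
        report = {
            "n_taxa": int(self.rarefied.shape[0]),
            "n_samples": int(self.rarefied.shape[1]),
            "rarefaction_depth": cfg.rarefaction_depth,
            "dropped_samples": self.dropped_samples,
            "class_counts": self.classes.value_counts().to_dict(),
            "groups": [dataclasses.asdict(g) for g in self.groups],
        }
        dump_json(report, out / "prep.json")
        return report

    def stage_gradient(self) -> dict:
        cfg = self.config
        out = self.outdir / "gradient"
        out.mkdir(parents=True, exist_ok=True)
        meta = self.meta
        env_cols = [
            c
            for c in meta.columns
            if c not in ENV_COLUMNS_EXCLUDED and pd.api.types.is_numeric_dtype(meta[c])
        ]
        report: dict = {"geo_env": {}, "mantel": {}, "alpha_trends": {}}
        # geographic vs environmental distance, per transect
        if {"latitude", "longitude"}.issubset(meta.columns):
            transects = meta["transect"].unique() if "transect" in meta.columns else [None]
            for t in transects:
                sub = meta if t is None else meta[meta["transect"] == t]
                if len(sub) < 3:
                    continue
                key = "all" if t is None else f"transect_{t}"
                report["geo_env"][key] = {
                    var: dataclasses.asdict(geo_env_correlation(sub, var)) for var in env_cols
                }
        # Mantel: Bray-Curtis community distance vs per-variable Euclidean
        # distance on the z-scored variable
        d_comm = bray_curtis_matrix(relative_abundance(self.rarefied))
        rng = np.random.default_rng(cfg.seed)
        for var in env_cols:
            v = meta[var].to_numpy(dtype=float)
            if np.ptp(v) == 0:
                continue
            z = (v - v.mean()) / v.std()
            d_env = squareform(pdist(z[:, None], metric="euclidean"))
            res = mantel_test(
                d_comm, d_env, n_permutations=cfg.mantel_permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            report["mantel"][var] = dataclasses.asdict(res)
        # alpha diversity trends vs salinity
        sal = meta["salinity"].to_numpy(dtype=float)
        alpha = pd.DataFrame(
            {
                "richness": alpha_diversity(self.rarefied, "richness"),
                "shannon": alpha_diversity(self.rarefied, "shannon"),
            }
        )
        alpha.to_csv(out / "alpha_diversity.csv")
        for metric in alpha.columns:
            report["alpha_trends"][metric] = _trend_dict(
                linear_trend(sal, alpha[metric].to_numpy(dtype=float))
            )
        dump_json(report, out / "gradient.json")
        return report

    def stage_biomarkers(self) -> dict:
        cfg = self.config
        out = self.outdir / "biomarkers"
        out.mkdir(parents=True, exist_ok=True)
        features = relative_abundance(self.rarefied)
        if cfg.taxonomy_path:
            counts = aggregate_taxonomy(self.rarefied, read_taxonomy_tsv(cfg.taxonomy_path))
            features = relative_abundance(counts)
        X = features.T  # samples x features
        y = self.meta["salinity"].to_numpy(dtype=float)
        sel = SalinityBiomarkerSelector(
            n_iterations=cfg.rf_iterations,
            n_estimators=cfg.rf_trees,
            cv_folds=cfg.cv_folds,
            cv_repeats=cfg.cv_repeats,
            n_grid=range(1, min(cfg.rf_grid_max, X.shape[1]) + 1),
            random_state=cfg.seed,
        ).fit(X, y)
        sel.importances_.rename("mean_importance").to_csv(out / "importance_ranking.csv")
        sel.cv_error_curve_.to_csv(out / "cv_error_curve.csv", index=False)
        fit = linear_trend(y, sel.predict(X))
        report = {
            "selected_n": sel.selected_n_,
            "biomarkers": sel.biomarkers_,
            "colonizer_labels": sel.colonizer_labels_,
            "training_fit_r_squared": fit.r_squared,
            "n_iterations": cfg.rf_iterations,
            "n_trees": cfg.rf_trees,
        }
        dump_json(report, out / "biomarkers.json")
        return report

    def stage_networks(self) -> dict:
        self._networks()
        out = self.outdir / "networks"
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for net, grp, topo in zip(self.nets, self.net_groups, self.topologies):
            write_network(net, out / f"network_{grp.group_id}.graphml", fmt="graphml")
            write_network(net, out / f"network_{grp.group_id}.tsv", fmt="tsv")
            rows.append({"group_id": grp.group_id, "mean_salinity": grp.mean_salinity,
                         **dataclasses.asdict(topo)})
        topo_df = pd.DataFrame(rows)
        topo_df.to_csv(out / "topology.csv", index=False)
        report = {"topology": rows, "trends": {}}
        if len(rows) >= 3:
            sal = topo_df["mean_salinity"].to_numpy(dtype=float)
            for metric in (
                "n_nodes", "n_links", "avg_degree", "avg_clustering",
                "density", "connectedness", "modularity", "n_modules",
            ):
                vals = topo_df[metric].to_numpy(dtype=float)
                if np.isfinite(vals).sum() >= 3:
                    report["trends"][metric] = _trend_dict(
                        linear_trend(sal[np.isfinite(vals)], vals[np.isfinite(vals)])
                    )
        dump_json(report, out / "networks.json")
        return report

    def stage_stability(self) -> dict:
        cfg = self.config
        self._networks()
        out = self.outdir / "stability"
        out.mkdir(parents=True, exist_ok=True)
        rng = np.random.default_rng(cfg.seed)
        results, recs = [], []
        for net, grp in zip(self.nets, self.net_groups):
            res = removal_simulation(
                net,
                cfg.removal_fractions,
                n_replicates=cfg.n_removal_replicates,
                seed=int(rng.integers(2**31 - 1)),
            )
            results.append(res)
            r = res.records.copy()
            r.insert(0, "group_id", grp.group_id)
            recs.append(r)
        pd.concat(recs).to_csv(out / "removal_records.csv", index=False)
        report = {"trends": {}}
        sal = [g.mean_salinity for g in self.net_groups]
        if len(results) >= 3:
            for p in cfg.removal_fractions:
                report["trends"][f"fraction_{p}"] = {
                    metric: _trend_dict(stability_trend(results, sal, p, metric))
                    for metric in ("avg_degree", "natural_connectivity")
                }
        dump_json(report, out / "stability.json")
        self.robustness = results
        return report

    def stage_turnover(self) -> dict:
        cfg = self.config
        self._networks()
        out = self.outdir / "turnover"
        out.mkdir(parents=True, exist_ok=True)
        comms = [
            make_community(net, self.rarefied, grp, self.classes)
            for net, grp in zip(self.nets, self.net_groups)
        ]
        report = {"communities": [], "adjacent_overlaps": [], "pairwise_similarity": []}
        for c in comms:
            report["communities"].append(
                {
                    "network_id": c.network_id,
                    "n_nodes": len(c.nodes),
                    "class_proportions": {
                        k: float(v)
                        for k, v in pd.Series(list(c.classes.values()))
                        .value_counts(normalize=True)
                        .items()
                    },
                }
            )
        for c1, c2 in zip(comms[:-1], comms[1:]):
            ov = community_overlap(c1, c2)
            report["adjacent_overlaps"].append(
                {
                    "pair": [c1.network_id, c2.network_id],
                    "n_overlap": len(ov.overlap),
                    "n_unique_first": len(ov.unique_to_first),
                    "n_unique_second": len(ov.unique_to_second),
                    "overlap_classes": ov.overlap_classes,
                }
            )
        for i in range(len(comms)):
            for j in range(i + 1, len(comms)):
                report["pairwise_similarity"].append(
                    {
                        "pair": [comms[i].network_id, comms[j].network_id],
                        "salinity_span": abs(comms[i].mean_salinity - comms[j].mean_salinity),
                        "similarity": community_similarity(
                            comms[i], comms[j], mode=cfg.similarity_mode
                        ),
                    }
                )
        if len(comms) >= 3:
            report["trend"] = _trend_dict(turnover_trend(comms, mode=cfg.similarity_mode))
        dump_json(report, out / "turnover.json")
        self.communities = comms
        return report

    def stage_roles(self) -> dict:
        self._networks()
        out = self.outdir / "roles"
        out.mkdir(parents=True, exist_ok=True)
        recs = [relative_degree(net, self.classes) for net in self.nets]
        pd.concat(recs).to_csv(out / "relative_degree_records.csv", index=False)
        report = {}
        if len(recs) >= 3:
            trends = role_trends(recs, [g.mean_salinity for g in self.net_groups])
            report["trends"] = {k: _trend_dict(v) for k, v in trends.items()}
        breadth = levins_breadth(self.rarefied, classes=self.classes)
        breadth.to_csv(out / "niche_breadth.csv")
        stat, p = breadth_comparison(breadth)
        report["niche_breadth_wilcoxon"] = {"statistic": stat, "p_value": p}
        report["mean_breadth_by_class"] = (
            breadth.groupby("abundance_class")["levins_B"].mean().to_dict()
        )
        dump_json(report, out / "roles.json")
        return report

    # -- driver ----------------------------------------------------------------
    def run(self, stages=None) -> dict:
        stages = list(stages) if stages is not None else list(ALL_STAGES)
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.outdir.mkdir(parents=True, exist_ok=True)
        try:
            self._prepare()
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("prep", exc) from exc
        reports = {}
        for stage in ALL_STAGES:
            if stage not in stages:
                continue
            fn = getattr(self, f"stage_{stage}")
            try:
                reports[stage] = fn()
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(stage, exc) from exc
        provenance = {
            "config": self.config.to_dict(),
            "config_digest": self.config.digest(),
            "seed": self.config.seed,
            "salinet_version": __version__,
            "numpy_version": np.__version__,
            "stages_run": [s for s in ALL_STAGES if s in stages],
        }
        dump_json(provenance, self.outdir / "provenance.json")
        return reports


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    return Pipeline(config).run(stages=stages)
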