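"""End-to-end orchestration: simulate or ingest, then analyze.

A single :class:`AnalysisConfig` drives the chain — rarefaction, alpha and
beta diversity, host covariate matrices, Mantel/partial Mantel/MRM/
PERMANOVA, the phylosymbiosis co-dendrogram test, and the co-occurrence
network — producing a JSON-serializable :class:`AnalysisReport`. Per-stage
seeds are derived from the master seed and a stable hash of the stage
name, so adding a stage never perturbs the randomness of earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from phylosym import io as psio
from phylosym.datamodel import FeatureTable, SampleMetadata, metadata_frame
from phylosym import diversity
from phylosym.covariates import (CovariateSet, covariates_from_metadata,
                                 k2p_distance, expand_to_samples)
from phylosym import inference
from phylosym import phylosymbiosis as psym
from phylosym import network as coonet
from phylosym.simulate import SimulationConfig, simulate_communities

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_pipeline", "stage_seed", "load_config"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed and stage name."""
    digest = hashlib.sha256(stage.encode()).digest()
    return (master_seed * 1_000_003 + int.from_bytes(digest[:4], "big")) \
        % (2 ** 31)


@dataclass
class AnalysisConfig:
    seed: int = 0
    # either simulate…
    simulate: Mapping[str, Any] | None = None
    # …or ingest
    table_path: str | None = None
    metadata_path: str | None = None
    microbial_tree_path: str | None = None
    host_tree_path: str | None = None
    host_alignment_path: str | None = None
    genetics_path: str | None = None
    gamma_shape: float | None = 3.0
    # analysis settings
    rarefaction_depth: int | None = None
    metrics: Sequence[str] = ("jaccard", "bray_curtis",
                              "unweighted_unifrac", "weighted_unifrac")
    n_perm: int = 999
    n_random_trees: int = 10000
    phylosymbiosis_mode: str = "population_mean"
    n_picks: int = 100
    run_network: bool = True
    run_sensitivity: bool = False
    n_subsamples: int = 100
    per_population: int = 3
    permanova_grouping: str = "host_plant"

    def validate(self) -> None:
        if self.simulate is None and self.table_path is None:
            raise ValueError("config needs either a simulate section or "
                             "input paths")
        needs_tree = any(m.endswith("unifrac") for m in self.metrics)
        if self.simulate is None:
            for name in ("table_path", "metadata_path", "host_tree_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
            if needs_tree and self.microbial_tree_path is None:
                raise ValueError("UniFrac metrics requested without a "
                                 "microbial tree")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from a flat TOML file."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = AnalysisConfig(**raw)
    cfg.validate()
    return cfg


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: AnalysisConfig,
                 out_dir: str | Path | None = None) -> dict:
    """Execute all requested stages in dependency order.

    Returns (and optionally writes) a JSON-serializable report. Optional
    stages that fail are recorded under ``errors`` instead of aborting the
    run; label misalignment between inputs is fatal before any computation.
    """
    config.validate()
    report: dict[str, Any] = {"provenance": {
        "seed": config.seed,
        "config": _jsonable(asdict(config)),
    }}
    errors: dict[str, str] = {}

    # ---- inputs ------------------------------------------------------
    if config.simulate is not None:
        sim_cfg = SimulationConfig(
            seed=stage_seed(config.seed, "simulate"),
            **{k: v for k, v in dict(config.simulate).items() if k != "seed"})
        ds = simulate_communities(sim_cfg)
        table, metadata = ds.table, list(ds.metadata)
        host_tree, microbial_tree = ds.host_tree, ds.microbial_tree
        genetics = host_tree.tip_tip_distances()
        report["simulate"] = {"truth": _jsonable(
            {k: v for k, v in ds.truth.items()
             if k not in ("baseline", "phylo_effects")})}
    else:
        table = psio.read_feature_table(config.table_path)
        metadata = psio.read_metadata(config.metadata_path)
        host_tree = (psio.read_newick(Path(config.host_tree_path))
                     if config.host_tree_path else None)
        microbial_tree = (psio.read_newick(Path(config.microbial_tree_path))
                          if config.microbial_tree_path else None)
        if config.genetics_path:
            genetics = psio.read_distance_matrix(config.genetics_path)
        elif config.host_alignment_path:
            aln = psio.read_alignment(config.host_alignment_path)
            genetics = k2p_distance(aln, gamma_shape=config.gamma_shape)
        elif host_tree is not None:
            genetics = host_tree.tip_tip_distances()
        else:
            genetics = None
    md_ids = {m.sample_id for m in metadata}
    missing = [s for s in table.sample_ids if s not in md_ids]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    metadata = [m for m in metadata if m.sample_id in set(table.sample_ids)]

    # ---- rarefaction -------------------------------------------------
    if config.rarefaction_depth:
        table = diversity.rarefy(table, config.rarefaction_depth,
                                 seed=stage_seed(config.seed, "rarefy"))
        metadata = [m for m in metadata
                    if m.sample_id in set(table.sample_ids)]
        report["rarefy"] = {"depth": config.rarefaction_depth,
                            "n_samples": len(table.sample_ids)}
    metadata.sort(key=lambda m: table.sample_ids.index(m.sample_id))

    # ---- alpha -------------------------------------------------------
    alpha_df = diversity.alpha_table(table)
    report["alpha"] = _jsonable(alpha_df.to_dict())
    groups_plant = {m.sample_id: m.host_plant for m in metadata}
    if len(set(groups_plant.values())) >= 2:
        try:
            gt = inference.group_tests(
                dict(zip(alpha_df.index, alpha_df["shannon"])), groups_plant)
            report["alpha_group_tests"] = {
                "metric": "shannon", "grouping": "host_plant",
                "kruskal_h": gt.kruskal_h, "kruskal_p": gt.kruskal_p,
                "dunn_p_adj": _jsonable(
                    {f"{a}|{b}": p for (a, b), p in gt.dunn_p_adj.items()}),
            }
        except ValueError as exc:
            errors["alpha_group_tests"] = str(exc)

    # ---- beta + ordination -------------------------------------------
    beta_dms = {}
    for metric in config.metrics:
        try:
            beta_dms[metric] = diversity.beta(table, metric,
                                              tree=microbial_tree)
        except ValueError as exc:
            errors[f"beta:{metric}"] = str(exc)
    report["beta"] = {m: {"mean": float(np.mean(dm.condensed_form()))}
                      for m, dm in beta_dms.items()}
    if beta_dms:
        first = next(iter(beta_dms))
        ord_res = diversity.pcoa(beta_dms[first])
        report["pcoa"] = {
            "metric": first,
            "proportion_explained": _jsonable(
                ord_res.proportion_explained[:3].tolist()),
        }

    # ---- covariates --------------------------------------------------
    covset = None
    if genetics is not None:
        try:
            covset = covariates_from_metadata(metadata, genetics)
        except (ValueError, KeyError) as exc:
            errors["covariates"] = str(exc)

    # ---- matrix inference --------------------------------------------
    if covset is not None and beta_dms:
        mantel_out, mrm_out = {}, {}
        cov = covset.as_dict()
        for metric, dm in beta_dms.items():
            per_metric = {}
            for name, cdm in cov.items():
                controls = {k: v for k, v in cov.items() if k != name}
                try:
                    res = inference.partial_mantel(
                        dm, cdm, controls, n_perm=config.n_perm,
                        seed=stage_seed(config.seed,
                                        f"pmantel:{metric}:{name}"))
                    per_metric[name] = {"r": res.r, "p": res.p}
                except ValueError as exc:
                    per_metric[name] = {"error": str(exc)}
            mantel_out[metric] = per_metric
            try:
                res = inference.mrm(dm, cov, n_perm=config.n_perm,
                                    seed=stage_seed(config.seed,
                                                    f"mrm:{metric}"))
                mrm_out[metric] = {
                    "r_squared": res.r_squared,
                    "p_r_squared": res.p_r_squared,
                    "coefficients": _jsonable(dict(res.coefficients)),
                    "coefficient_p": _jsonable(dict(res.coefficient_p)),
                }
            except (ValueError, np.linalg.LinAlgError) as exc:
                errors[f"mrm:{metric}"] = str(exc)
        report["partial_mantel"] = mantel_out
        report["mrm"] = mrm_out

    groups = {m.sample_id: getattr(m, config.permanova_grouping)
              for m in metadata}
    if beta_dms and len(set(groups.values())) >= 2:
        perm_out = {}
        for metric, dm in beta_dms.items():
            try:
                res = inference.permanova(
                    dm, groups, n_perm=config.n_perm,
                    seed=stage_seed(config.seed, f"permanova:{metric}"))
                perm_out[metric] = {"pseudo_F": res.pseudo_f, "p": res.p}
            except ValueError as exc:
                errors[f"permanova:{metric}"] = str(exc)
        report["permanova"] = {"grouping": config.permanova_grouping,
                               **perm_out}

    # ---- phylosymbiosis ----------------------------------------------
    if host_tree is not None and beta_dms:
        mapping = {m.sample_id: m.population for m in metadata}
        psym_out = {}
        for metric, dm in beta_dms.items():
            try:
                if config.phylosymbiosis_mode == "random_pick":
                    res = psym.phylosymbiosis_test(
                        host_tree, table=table, mapping=mapping,
                        metric=metric, microbial_tree=microbial_tree,
                        mode="random_pick", n_picks=config.n_picks,
                        n_random=config.n_random_trees,
                        seed=stage_seed(config.seed, f"psym:{metric}"))
                else:
                    reps = psym.population_representatives(
                        table, mapping, mode="population_mean")
                    pdm = diversity.beta_frame(reps, metric,
                                               tree=microbial_tree)
                    res = psym.phylosymbiosis_test(
                        host_tree, pdm, metric=metric,
                        n_random=config.n_random_trees,
                        seed=stage_seed(config.seed, f"psym:{metric}"))
                psym_out[metric] = {"rf": res.rf_observed, "p": res.p,
                                    "mode": res.mode}
            except ValueError as exc:
                errors[f"phylosymbiosis:{metric}"] = str(exc)
        report["phylosymbiosis"] = psym_out

    # ---- sensitivity --------------------------------------------------
    if config.run_sensitivity and covset is not None:
        try:
            sens = inference.subsample_sensitivity(
                table, metadata, covset, test="partial_mantel",
                metric="bray_curtis", n_subsamples=config.n_subsamples,
                per_population=config.per_population, n_perm=config.n_perm,
                seed=stage_seed(config.seed, "sensitivity"))
            report["sensitivity"] = {
                "significant_fraction": sens.significant_fraction,
                "statistics": _jsonable(sens.statistics),
                "p_values": _jsonable(sens.p_values),
            }
        except ValueError as exc:
            errors["sensitivity"] = str(exc)

    # ---- network -------------------------------------------------------
    if config.run_network:
        try:
            net = coonet.build_network(table)
            report["network"] = {
                "n_nodes": net.graph.number_of_nodes(),
                "n_edges": net.graph.number_of_edges(),
                "n_modules": len(set(net.modules.values())),
                "role_counts": net.role_counts(),
                "module_algorithm": "greedy_modularity",
            }
        except ValueError as exc:
            errors["network"] = str(exc)

    if errors:
        report["errors"] = errors
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        psio.write_feature_table(table, out_dir / "table.tsv")
        metadata_frame(metadata).to_csv(out_dir / "metadata.tsv", sep="\t")
    return report
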