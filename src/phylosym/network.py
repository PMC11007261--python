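"""Co-occurrence networks and Zi–Pi keystone classification.

Construction follows the common amplicon-platform recipe: drop rare taxa
(present in fewer than 5 samples), keep the top 100 taxa by mean relative
abundance, connect pairs whose Pearson correlation across samples is
strong (|r| > 0.6) and significant (two-sided p < 0.05). Modules come from
greedy modularity maximization; each node's within-module degree z-score
(Zi) and among-module participation coefficient (Pi) place it into one of
four topological roles — peripherals, connectors, module hubs, network
hubs — the last three being keystone candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from phylosym.datamodel import FeatureTable

ROLES = ("peripheral", "connector", "module_hub", "network_hub")

__all__ = ["CooccurrenceGraph", "filter_taxa", "correlation_network",
           "detect_modules", "zi_pi", "classify_roles", "build_network",
           "ROLES"]


@dataclass(frozen=True)
class CooccurrenceGraph:
    """An undirected taxon co-occurrence graph with module/role annotation."""

    graph: nx.Graph
    modules: Mapping[str, int]
    node_stats: pd.DataFrame  # index: taxon; columns: degree, zi, pi, role

    def role_counts(self) -> dict[str, int]:
        counts = self.node_stats["role"].value_counts().to_dict()
        return {role: int(counts.get(role, 0)) for role in ROLES}


def filter_taxa(table: FeatureTable, min_occurrence: int = 5,
                top_n: int = 100) -> FeatureTable:
    """Occurrence and abundance filtering before network construction.

    Drops taxa present (count > 0) in fewer than ``min_occurrence``
    samples, then keeps the ``top_n`` taxa by mean relative abundance.
    Ties at the abundance cutoff break by taxon id order, so the result is
    deterministic.
    """
    occ = (table.counts > 0).sum(axis=0)
    keep = [t for t, o in zip(table.taxon_ids, occ) if o >= min_occurrence]
    if not keep:
        raise ValueError(
            f"no taxa present in at least {min_occurrence} samples")
    sub = table.filter_taxa(keep)
    mean_rel = sub.relative_abundance().mean(axis=0)
    ranked = sorted(zip(sub.taxon_ids, mean_rel),
                    key=lambda tr: (-tr[1], tr[0]))
    chosen = [t for t, _ in ranked[:top_n]]
    return sub.filter_taxa(sorted(chosen))


def correlation_network(table: FeatureTable, r_threshold: float = 0.6,
                        p_threshold: float = 0.05, clr: bool = False,
                        bh_correct: bool = False) -> nx.Graph:
    """Pearson correlation graph over taxa.

    Correlations are computed between per-sample relative abundances (or
    centered log-ratios with pseudocount 0.5 when ``clr`` is set, a
    compositionality-aware alternative). An edge is kept iff |r| exceeds
    ``r_threshold`` and its two-sided t-test p is below ``p_threshold``
    (optionally Benjamini–Hochberg adjusted). Zero-variance taxa are
    excluded with a warning. All retained taxa appear as nodes, including
    isolated ones.
    """
    n_samples = len(table.sample_ids)
    if n_samples < 4:
        raise ValueError("correlation p-values unstable below 4 samples")
    if clr:
        comp = table.counts + 0.5
        comp = comp / comp.sum(axis=1, keepdims=True)
        x = np.log(comp)
        x = x - x.mean(axis=1, keepdims=True)
    else:
        x = table.relative_abundance()
    sd = x.std(axis=0)
    constant = [t for t, s in zip(table.taxon_ids, sd) if s == 0]
    if constant:
        warnings.warn(f"excluding {len(constant)} zero-variance taxa from "
                      "the correlation network", stacklevel=2)
    taxa = [t for t in table.taxon_ids if t not in set(constant)]
    cols = [i for i, t in enumerate(table.taxon_ids) if t in set(taxa)]
    xs = x[:, cols]
    r = np.corrcoef(xs, rowvar=False)
    np.clip(r, -1.0, 1.0, out=r)
    dof = n_samples - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = r * np.sqrt(dof / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t_stat), dof)
    iu = np.triu_indices(len(taxa), k=1)
    p_flat = p[iu]
    if bh_correct and len(p_flat):
        _, p_flat, _, _ = multipletests(p_flat, method="fdr_bh")
    g = nx.Graph()
    g.add_nodes_from(taxa)
    for (i, j), p_ij in zip(zip(*iu), p_flat):
        r_ij = r[i, j]
        if abs(r_ij) > r_threshold and p_ij < p_threshold:
            g.add_edge(taxa[i], taxa[j], r=float(r_ij), p=float(p_ij),
                       weight=abs(float(r_ij)))
    return g


def detect_modules(graph: nx.Graph) -> dict[str, int]:
    """Greedy modularity-maximization module assignment.

    Isolated nodes become singleton modules. Module ids are renumbered by
    the lexicographically smallest member, so the labeling is deterministic.
    """
    connected = [n for n in graph.nodes if graph.degree(n) > 0]
    communities: list[set] = []
    if connected:
        sub = graph.subgraph(connected)
        communities = [set(c) for c in
                       nx.community.greedy_modularity_communities(sub)]
    for n in graph.nodes:
        if graph.degree(n) == 0:
            communities.append({n})
    communities.sort(key=lambda c: min(c))
    return {n: i for i, c in enumerate(communities) for n in sorted(c)}


def zi_pi(graph: nx.Graph, modules: Mapping[str, int]) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi = (k_own − mean k_own over the module) / sd; defined as 0 when the
    module has fewer than 3 members or zero spread. Pi = 1 − Σ_m
    (k_im/k_i)²; 0 for isolated nodes.
    """
    missing = [n for n in graph.nodes if n not in modules]
    if missing:
        raise KeyError(f"nodes without module assignment: {missing}")
    nodes = sorted(graph.nodes)
    k_own: dict[str, int] = {}
    k_per_module: dict[str, dict[int, int]] = {}
    for n in nodes:
        per: dict[int, int] = {}
        for nb in graph.neighbors(n):
            per[modules[nb]] = per.get(modules[nb], 0) + 1
        k_per_module[n] = per
        k_own[n] = per.get(modules[n], 0)
    by_module: dict[int, list[str]] = {}
    for n in nodes:
        by_module.setdefault(modules[n], []).append(n)
    zi = {}
    for mod, members in by_module.items():
        ks = np.array([k_own[m] for m in members], dtype=float)
        sd = ks.std()
        if len(members) < 3 or sd == 0:
            for m in members:
                zi[m] = 0.0
        else:
            mean = ks.mean()
            for m, k in zip(members, ks):
                zi[m] = float((k - mean) / sd)
    rows = []
    for n in nodes:
        k_total = graph.degree(n)
        if k_total == 0:
            pi = 0.0
        else:
            shares = np.array(list(k_per_module[n].values())) / k_total
            pi = float(1.0 - (shares ** 2).sum())
        rows.append({"taxon": n, "degree": int(k_total),
                     "module": modules[n], "zi": zi[n], "pi": pi})
    return pd.DataFrame(rows).set_index("taxon")


def classify_roles(stats_frame: pd.DataFrame, zi_cut: float = 2.5,
                   pi_cut: float = 0.62) -> pd.DataFrame:
    """Assign the four topological roles from Zi and Pi thresholds."""
    out = stats_frame.copy()
    hi_z = out["zi"] > zi_cut
    hi_p = out["pi"] > pi_cut
    role = np.where(hi_z & hi_p, "network_hub",
                    np.where(hi_z, "module_hub",
                             np.where(hi_p, "connector", "peripheral")))
    out["role"] = role
    return out


def build_network(table: FeatureTable, min_occurrence: int = 5,
                  top_n: int = 100, r_threshold: float = 0.6,
                  p_threshold: float = 0.05, zi_cut: float = 2.5,
                  pi_cut: float = 0.62, clr: bool = False,
                  bh_correct: bool = False) -> CooccurrenceGraph:
    """Filter → correlate → modules → Zi/Pi → roles, in one call."""
    filtered = filter_taxa(table, min_occurrence=min_occurrence, top_n=top_n)
    graph = correlation_network(filtered, r_threshold=r_threshold,
                                p_threshold=p_threshold, clr=clr,
                                bh_correct=bh_correct)
    modules = detect_modules(graph)
    stats_frame = classify_roles(zi_pi(graph, modules),
                                 zi_cut=zi_cut, pi_cut=pi_cut)
    return CooccurrenceGraph(graph=graph, modules=modules,
                             node_stats=stats_frame)
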