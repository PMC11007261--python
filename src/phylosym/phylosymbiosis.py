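"""Co-dendrogram test of phylosymbiosis.

Phylosymbiosis is the pattern in which microbial community dissimilarity
recapitulates host phylogeny. The test here: collapse samples to one
community profile per host population (population mean or a random pick),
cluster the population-level beta-diversity matrix with UPGMA, and score
topological congruence between the dendrogram and the host phylogeny by
the normalized Robinson–Foulds (RF) distance, with significance from the
RF distances of randomized topologies over the same leaf set. Smaller RF
than random means higher-than-chance congruence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from phylosym.datamodel import FeatureTable

__all__ = [
    "PhylosymbiosisResult", "population_representatives", "upgma",
    "robinson_foulds_normalized", "random_topology", "phylosymbiosis_test",
]


@dataclass(frozen=True)
class PhylosymbiosisResult:
    rf_observed: float
    p: float
    n_random: int
    metric: str
    mode: str
    rf_replicates: np.ndarray | None = None


# ------------------------------------------------------- representatives
def population_representatives(table: FeatureTable,
                               mapping: Mapping[str, str],
                               mode: str = "population_mean",
                               seed: int = 0) -> pd.DataFrame:
    """One relative-abundance profile per population.

    population_mean: the mean of the member samples' relative-abundance
    rows (each sample normalized first, so samples weigh equally regardless
    of depth). random_pick: one uniformly chosen member sample's profile.
    Returns a populations × taxa frame whose rows sum to 1.
    """
    if mode not in ("population_mean", "random_pick"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = [s for s in table.sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"samples without population: {missing}")
    rel = table.relative_abundance()
    by_pop: dict[str, list[int]] = {}
    for i, s in enumerate(table.sample_ids):
        by_pop.setdefault(mapping[s], []).append(i)
    empties = [p for p, rows in by_pop.items() if not rows]
    if empties:
        raise ValueError(f"empty populations: {empties}")
    rng = np.random.default_rng(seed)
    pops = sorted(by_pop)
    rows = []
    for pop in pops:
        idx = by_pop[pop]
        if mode == "population_mean":
            rows.append(rel[idx].mean(axis=0))
        else:
            rows.append(rel[int(rng.choice(idx))])
    return pd.DataFrame(rows, index=pops, columns=list(table.taxon_ids))


# ------------------------------------------------------------------ UPGMA
def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    Merge heights are half the average-linkage distance; ties are broken by
    the lexicographically smallest pair of cluster representatives, so the
    result is deterministic.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("UPGMA needs at least 3 labels")
    dist: dict[frozenset[int], float] = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[frozenset((i, j))] = float(dm.data[i, j])
    # cluster id -> (node, size, height, representative label)
    clusters: dict[int, tuple[TreeNode, int, float, str]] = {
        i: (TreeNode(name=labels[i]), 1, 0.0, labels[i]) for i in range(n)
    }
    next_id = n
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = dist[frozenset((i, j))]
            ri, rj = clusters[i][3], clusters[j][3]
            key = (d, *sorted((ri, rj)))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        d = dist[frozenset((i, j))]
        node_i, size_i, h_i, rep_i = clusters[i]
        node_j, size_j, h_j, rep_j = clusters[j]
        height = d / 2.0
        node_i.length = max(height - h_i, 0.0)
        node_j.length = max(height - h_j, 0.0)
        parent = TreeNode(children=[node_i, node_j])
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = \
                (size_i * dik + size_j * djk) / (size_i + size_j)
        del dist[frozenset((i, j))]
        del clusters[i], clusters[j]
        clusters[next_id] = (parent, size_i + size_j, height,
                             min(rep_i, rep_j))
        next_id += 1
    root = next(iter(clusters.values()))[0]
    root.length = None
    return root


# --------------------------------------------------------- Robinson–Foulds
def _bipartition_masks(tree: TreeNode, index: Mapping[str, int]) -> set[int]:
    """Non-trivial bipartitions as canonical bitmasks over the leaf index.

    The tree is treated as unrooted: each internal edge induces a split of
    the leaf set; masks are canonicalized to the side not containing leaf 0
    and splits with a singleton side are dropped.
    """
    n = len(index)
    full = (1 << n) - 1
    masks: set[int] = set()

    def walk(node: TreeNode) -> int:
        if node.is_tip():
            return 1 << index[node.name]
        mask = 0
        for child in node.children:
            mask |= walk(child)
        if mask & 1:
            canon = full ^ mask
        else:
            canon = mask
        size = canon.bit_count()
        if 2 <= size <= n - 2:
            masks.add(canon)
        return mask

    walk(tree)
    return masks


def robinson_foulds_normalized(t1: TreeNode, t2: TreeNode) -> float:
    """Normalized RF distance between two trees on the same leaf set.

    Trees are compared unrooted; the symmetric difference of non-trivial
    bipartitions is divided by 2(n−3), the maximum attainable between
    fully resolved trees, so the result lies in [0, 1].
    """
    tips1 = sorted(t.name for t in t1.tips())
    tips2 = sorted(t.name for t in t2.tips())
    if tips1 != tips2:
        diff = set(tips1) ^ set(tips2)
        raise ValueError(f"leaf sets differ: {sorted(diff)}")
    n = len(tips1)
    if n < 4:
        raise ValueError("RF comparison needs at least 4 leaves")
    index = {name: i for i, name in enumerate(tips1)}
    b1 = _bipartition_masks(t1, index)
    b2 = _bipartition_masks(t2, index)
    return len(b1 ^ b2) / (2.0 * (n - 3))


# ------------------------------------------------------------ random trees
def _random_join_masks(n: int, rng: np.random.Generator) -> set[int]:
    """Bipartition set of a random sequential-coalescence topology."""
    full = (1 << n) - 1
    clusters = [1 << i for i in range(n)]
    masks: set[int] = set()
    while len(clusters) > 1:
        i, j = rng.choice(len(clusters), size=2, replace=False)
        merged = clusters[i] | clusters[j]
        for k in sorted((i, j), reverse=True):
            clusters.pop(k)
        clusters.append(merged)
        canon = (full ^ merged) if merged & 1 else merged
        size = canon.bit_count()
        if 2 <= size <= n - 2:
            masks.add(canon)
    return masks


def random_topology(labels: Sequence[str], seed: int) -> TreeNode:
    """Uniform random sequential binary topology over ``labels``.

    Lineage pairs coalesce uniformly at random (the topology of a labeled
    coalescent); unit branch lengths, which RF comparisons ignore.
    """
    labels = list(labels)
    if len(labels) < 4:
        raise ValueError("need at least 4 labels")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    nodes = [TreeNode(name=labels[k], length=1.0) for k in order]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        merged = TreeNode(children=[nodes[i], nodes[j]], length=1.0)
        for k in sorted((i, j), reverse=True):
            nodes.pop(k)
        nodes.append(merged)
    root = nodes[0]
    root.length = None
    return root


# ------------------------------------------------------------- the test
def phylosymbiosis_test(host_tree: TreeNode,
                        beta_dm: DistanceMatrix | None = None,
                        *,
                        table: FeatureTable | None = None,
                        mapping: Mapping[str, str] | None = None,
                        metric: str = "bray_curtis",
                        microbial_tree: TreeNode | None = None,
                        mode: str = "population_mean",
                        n_picks: int = 100,
                        n_random: int = 10000,
                        seed: int = 0) -> PhylosymbiosisResult:
    """Dendrogram–phylogeny congruence test.

    With a population-level ``beta_dm`` (population_mean mode): one UPGMA
    dendrogram, one observed RF. With ``mode='random_pick'`` and a
    sample-level ``table`` + population ``mapping``: ``n_picks``
    dendrograms from random one-sample-per-population representatives, the
    mean RF reported as the observed statistic with the replicate vector
    retained. The host tree is pruned to the shared population set.

    p = (#{RF_random ≤ RF_observed} + 1) / (n_random + 1): the alternative
    is that the dendrogram is *more* congruent with the host tree than a
    random topology.
    """
    rng = np.random.default_rng(seed)
    replicates = None
    if mode == "random_pick":
        if table is None or mapping is None:
            raise ValueError("random_pick mode needs table and mapping")
        from phylosym.diversity import beta_frame

        pops = sorted(set(mapping[s] for s in table.sample_ids))
        host = _pruned(host_tree, pops)
        replicates = np.empty(n_picks)
        for k in range(n_picks):
            reps = population_representatives(
                table, mapping, mode="random_pick",
                seed=int(rng.integers(2 ** 31)))
            pdm = beta_frame(reps, metric, tree=microbial_tree)
            dendro = upgma(pdm)
            replicates[k] = robinson_foulds_normalized(host, dendro)
        rf_obs = float(replicates.mean())
        labels = pops
    else:
        if beta_dm is None:
            raise ValueError("population_mean mode needs beta_dm")
        labels = sorted(beta_dm.ids)
        host = _pruned(host_tree, labels)
        dendro = upgma(beta_dm.filter(labels))
        rf_obs = robinson_foulds_normalized(host, dendro)
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 shared populations")
    index = {name: i for i, name in enumerate(sorted(labels))}
    host_masks = _bipartition_masks(host, index)
    norm = 2.0 * (n - 3)
    count_le = 0
    for _ in range(n_random):
        rmasks = _random_join_masks(n, rng)
        rf_rand = len(host_masks ^ rmasks) / norm
        if rf_rand <= rf_obs + 1e-12:
            count_le += 1
    p = (count_le + 1.0) / (n_random + 1.0)
    return PhylosymbiosisResult(rf_observed=rf_obs, p=p, n_random=n_random,
                                metric=metric, mode=mode,
                                rf_replicates=replicates)


def _pruned(host_tree: TreeNode, labels: Sequence[str]) -> TreeNode:
    tips = {t.name for t in host_tree.tips()}
    missing = [l for l in labels if l not in tips]
    if missing:
        raise ValueError(f"populations missing from host tree: {missing}")
    if set(labels) == tips:
        return host_tree
    return host_tree.shear(list(labels))
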