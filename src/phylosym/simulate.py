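"""Paired host-phylogeny + microbiome co-simulation.

The generator produces everything the analysis chain consumes: a host tree
over populations, a microbial tree over taxa, a multi-population count
table with multinomial sequencing noise, and sample metadata with
geographic, altitude, and diet covariates.

Generative model, for taxon i in population j:

    mu_ij = b_i + sigma_phylo * g_i(j) + sigma_diet * delta_i * I(diet_j = A)

where b_i is a taxon baseline (coupled to terminal branch length, plus a
Normal residual, and offset downward for diet-responsive taxa so their
clades are rare without the diet), g_i is an independent Brownian-motion
realization on the host tree (unit-time variance 1, root height 1), and
delta_i marks diet-responsive taxa. Sample s in population j adds
taxon-wise noise eps_is ~ Normal(0, sigma_noise^2) and draws its counts as
Multinomial(depth, softmax_i(mu_ij + eps_is)).

Brownian motion on the host tree makes community similarity decay with
host phylogenetic distance — the signal that Mantel-type and co-dendrogram
phylosymbiosis tests target. The diet effect can load on whole deep
microbial clades ("deep" mode, emulating diet structuring ancient clades,
which phylogenetically weighted beta metrics should pick up preferentially)
or on scattered singleton leaves ("shallow").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from phylosym.datamodel import FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_host_tree",
           "simulate_microbial_tree", "assign_covariates",
           "simulate_communities"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the co-simulation.

    Defaults emulate the motivating study design: a dozen host populations
    of 3–5 pooled samples each, sequencing depth at the rarefaction depth
    35,701, moderate within-population noise, and a clade-conserved binary
    diet covariate splitting the host tree roughly in half.
    """

    n_populations: int = 12
    samples_per_population: int = 4
    n_taxa: int = 200
    depth: int = 35_701
    sigma_phylo: float = 1.0
    sigma_diet: float = 1.0
    diet_clade_depth: str = "deep"
    sigma_noise: float = 0.5
    diet_split: float = 0.5
    diet_taxa_fraction: float = 0.1
    branch_abundance_coupling: float = 1.5
    baseline_sd: float = 0.5
    diet_rarity_offset: float = 1.0
    bounding_box: tuple[float, float, float, float] = (27.0, 40.0, 90.0, 120.0)
    altitude_by_diet: tuple[float, float] = (3200.0, 900.0)
    altitude_sd: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 4:
            raise ValueError("need at least 4 populations")
        if self.samples_per_population < 3:
            raise ValueError("need at least 3 samples per population")
        if self.n_taxa < 20:
            raise ValueError("need at least 20 taxa")
        if self.depth < 100:
            raise ValueError("depth must be at least 100")
        for name in ("sigma_phylo", "sigma_diet", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.diet_clade_depth not in ("deep", "shallow"):
            raise ValueError("diet_clade_depth must be 'deep' or 'shallow'")
        if not 0.0 < self.diet_split < 1.0:
            raise ValueError("diet_split must be in (0, 1)")
        if not 0.0 < self.diet_taxa_fraction <= 0.5:
            raise ValueError("diet_taxa_fraction must be in (0, 0.5]")


@dataclass(frozen=True)
class SyntheticDataset:
    host_tree: TreeNode
    microbial_tree: TreeNode
    table: FeatureTable
    metadata: tuple[SampleMetadata, ...]
    truth: dict


# ------------------------------------------------------------ tree growth
def _yule_tree(labels: Sequence[str], rng: np.random.Generator) -> TreeNode:
    """Pure-birth tree: uniform lineage splits, exponential waiting times,
    branch lengths rescaled so the root height is exactly 1."""
    n = len(labels)
    # active lineages as (node, birth_time); root has two children at t=0
    root = TreeNode()
    active: list[tuple[TreeNode, float]] = []
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(k))
        node, birth = active.pop(idx)
        node.length = t - birth
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            active.append((child, t))
    present = t + rng.exponential(1.0 / n)
    order = rng.permutation(n)
    for (node, birth), k in zip(active, order):
        node.length = present - birth
        node.name = labels[k]
    # rescale to root height 1
    for node in root.traverse(include_self=False):
        node.length /= present
    return root


def simulate_host_tree(n_populations: int, seed: int) -> TreeNode:
    """Yule tree over populations P01..Pn, root height 1."""
    if n_populations < 4:
        raise ValueError("need at least 4 populations")
    labels = [f"P{i + 1:02d}" for i in range(n_populations)]
    return _yule_tree(labels, np.random.default_rng([seed, 101]))


def simulate_microbial_tree(n_taxa: int, seed: int) -> TreeNode:
    """Yule tree over taxa T001..Tn, root height 1."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    labels = [f"T{i + 1:03d}" for i in range(n_taxa)]
    return _yule_tree(labels, np.random.default_rng([seed, 202]))


# ------------------------------------------------------------- covariates
def assign_covariates(host_tree: TreeNode,
                      config: SimulationConfig) -> pd.DataFrame:
    """Population-level covariates: clade-conserved diet, geography, altitude.

    Diet A is assigned to the clade whose leaf count is closest to
    diet_split of the tree (the nearest achievable split is used and logged
    when no clade matches within one leaf). Coordinates are uniform in the
    bounding box; altitude is drawn around a diet-specific mean, emulating
    a high-altitude vs low-altitude host split.
    """
    rng = np.random.default_rng([config.seed, 303])
    leaves = [t.name for t in host_tree.tips()]
    n = len(leaves)
    if n < 4:
        raise ValueError("host tree needs at least 4 leaves")
    target = config.diet_split * n
    best_clade, best_err = None, np.inf
    for node in host_tree.non_tips(include_self=False):
        clade = [t.name for t in node.tips()]
        if len(clade) >= n:
            continue
        err = abs(len(clade) - target)
        if err < best_err:
            best_clade, best_err = clade, err
    if best_err > 1.0:
        logger.warning(
            "no clade within ±1 leaf of requested diet split %.2f; "
            "using nearest achievable (%d of %d leaves)",
            config.diet_split, len(best_clade), n)
    diet_a = set(best_clade)
    lat_lo, lat_hi, lon_lo, lon_hi = config.bounding_box
    alt_a, alt_b = config.altitude_by_diet
    rows = []
    for pop in sorted(leaves):
        diet = "A" if pop in diet_a else "B"
        rows.append({
            "population": pop,
            "diet": diet,
            "latitude": rng.uniform(lat_lo, lat_hi),
            "longitude": rng.uniform(lon_lo, lon_hi),
            "altitude": (alt_a if diet == "A" else alt_b)
            + rng.normal(0.0, config.altitude_sd),
        })
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------- diet taxa sets
def _node_age(node: TreeNode) -> float:
    """Height of a node above the leaves (tree assumed ultrametric)."""
    tip = next(node.tips(), None)
    if tip is None:
        return 0.0
    age = 0.0
    cur = tip
    while cur is not node:
        age += cur.length or 0.0
        cur = cur.parent
    return age


def _diet_taxa(microbial_tree: TreeNode, config: SimulationConfig,
               rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Select diet-responsive taxa; returns (taxa, clade descriptions)."""
    leaves = sorted(t.name for t in microbial_tree.tips())
    n = len(leaves)
    target = max(2, int(round(config.diet_taxa_fraction * n)))
    limit = n // 2
    if config.diet_clade_depth == "shallow":
        chosen = sorted(rng.choice(leaves, size=min(target, limit),
                                   replace=False))
        return chosen, [f"singleton:{t}" for t in chosen]
    internal = [nd for nd in microbial_tree.non_tips(include_self=False)]
    ages = np.array([_node_age(nd) for nd in internal])
    threshold = np.quantile(ages, 0.75)
    candidates = [nd for nd, a in zip(internal, ages) if a >= threshold]
    order = rng.permutation(len(candidates))
    chosen_taxa: set[str] = set()
    clades: list[str] = []
    for idx in order:
        if len(clades) >= 3:
            break
        clade = sorted(t.name for t in candidates[idx].tips())
        if chosen_taxa & set(clade):
            continue
        if len(chosen_taxa) + len(clade) > limit:
            continue
        chosen_taxa.update(clade)
        clades.append(f"clade:{len(clade)}:{clade[0]}")
        if len(chosen_taxa) >= target:
            break
    if not chosen_taxa:
        # all old clades too large: fall back to the smallest candidate
        smallest = min(candidates, key=lambda nd: nd.count(tips=True))
        chosen_taxa = {t.name for t in smallest.tips()}
        chosen_taxa = set(sorted(chosen_taxa)[:limit])
        clades = [f"clade:{len(chosen_taxa)}:truncated"]
    return sorted(chosen_taxa), clades


# -------------------------------------------------------- Brownian motion
def _brownian_on_tree(tree: TreeNode, n_traits: int,
                      rng: np.random.Generator,
                      leaf_order: Sequence[str]) -> np.ndarray:
    """n_traits independent BM realizations; returns (n_traits, n_leaves)."""
    values: dict[int, np.ndarray] = {id(tree): np.zeros(n_traits)}
    out = np.empty((n_traits, len(leaf_order)))
    col = {name: k for k, name in enumerate(leaf_order)}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        step = rng.normal(0.0, np.sqrt(max(node.length or 0.0, 0.0)),
                          size=n_traits)
        val = parent_val + step
        if node.is_tip():
            out[:, col[node.name]] = val
        else:
            values[id(node)] = val
    return out


# ------------------------------------------------------------- main entry
def simulate_communities(config: SimulationConfig) -> SyntheticDataset:
    """Run the full co-simulation; deterministic in ``config.seed``."""
    host_tree = simulate_host_tree(config.n_populations, config.seed)
    microbial_tree = simulate_microbial_tree(config.n_taxa, config.seed)
    covariates = assign_covariates(host_tree, config)
    rng = np.random.default_rng([config.seed, 404])

    pops = sorted(t.name for t in host_tree.tips())
    taxa = sorted(t.name for t in microbial_tree.tips())
    n_pops, n_taxa = len(pops), len(taxa)

    # Baseline log-abundance couples to terminal branch length: short
    # terminal branches mark fine-scale sequence variants of abundant
    # lineages, which in amplicon data are the rare, detection-boundary
    # taxa. The coupling puts presence/absence sampling noise on short
    # branches, where phylogenetic metrics discount it.
    tip_len = {t.name: (t.length or 0.0) for t in microbial_tree.tips()}
    tl = np.array([tip_len[t] for t in taxa])
    z = (tl - tl.mean()) / tl.std() if tl.std() > 0 else np.zeros(n_taxa)
    baseline = (config.branch_abundance_coupling * z
                + rng.normal(0.0, config.baseline_sd, size=n_taxa))
    g = _brownian_on_tree(host_tree, n_taxa, rng, pops)  # (taxa, pops)
    diet_taxa, diet_clades = _diet_taxa(microbial_tree, config, rng)
    delta = np.array([1.0 if t in set(diet_taxa) else 0.0 for t in taxa])
    # Diet-responsive clades are rare without their diet: offsetting their
    # baseline by sigma_diet + diet_rarity_offset puts them near/below
    # detection in diet-B populations and ordinarily abundant in diet-A,
    # so the effect reaches presence/absence as well as abundance.
    baseline = baseline - (config.sigma_diet + config.diet_rarity_offset) \
        * delta
    diet_flag = np.array([1.0 if covariates.loc[p, "diet"] == "A" else 0.0
                          for p in pops])

    # mu[taxon, pop]
    mu = (baseline[:, None] + config.sigma_phylo * g
          + config.sigma_diet * delta[:, None] * diet_flag[None, :])

    sample_ids: list[str] = []
    counts = np.empty((n_pops * config.samples_per_population, n_taxa),
                      dtype=np.int64)
    metadata: list[SampleMetadata] = []
    row = 0
    for j, pop in enumerate(pops):
        cov = covariates.loc[pop]
        for s in range(config.samples_per_population):
            eps = rng.normal(0.0, config.sigma_noise, size=n_taxa)
            logit = mu[:, j] + eps
            logit -= logit.max()  # softmax underflow guard
            p = np.exp(logit)
            p /= p.sum()
            counts[row] = rng.multinomial(config.depth, p)
            sid = f"{pop}_s{s + 1}"
            sample_ids.append(sid)
            metadata.append(SampleMetadata(
                sample_id=sid, population=pop, species=f"sp_{pop}",
                latitude=float(cov["latitude"]),
                longitude=float(cov["longitude"]),
                altitude=float(cov["altitude"]),
                host_plant=("Crassulaceae" if cov["diet"] == "A"
                            else "Papaveraceae"),
            ))
            row += 1
    table = FeatureTable(tuple(sample_ids), tuple(taxa), counts)
    truth = {
        "config": asdict(config),
        "diet_taxa": diet_taxa,
        "diet_clades": diet_clades,
        "diet_a_populations": sorted(p for p in pops
                                     if covariates.loc[p, "diet"] == "A"),
        "baseline": baseline.tolist(),
        "phylo_effects": g.tolist(),
    }
    return SyntheticDataset(host_tree=host_tree,
                            microbial_tree=microbial_tree,
                            table=table, metadata=tuple(metadata),
                            truth=truth)
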