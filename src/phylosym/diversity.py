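"""Rarefaction, alpha diversity, beta diversity, and PCoA.

Alpha metrics follow the amplicon-platform conventions: Shannon in log
base 2 by default, classic Chao1 with the bias-corrected fallback when no
doubletons are present, Simpson as 1 − Σp², Good's coverage as 1 − F1/N.
Beta metrics cover the two taxonomy-based measures (Jaccard on
presence/absence, Bray–Curtis on abundances) and the two phylogenetic ones
(unweighted and weighted UniFrac on a shared microbial tree).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity as _skbio_beta
from skbio.stats.ordination import OrdinationResults, pcoa as _skbio_pcoa

from phylosym.datamodel import FeatureTable

logger = logging.getLogger(__name__)

ALPHA_METRICS = ("observed", "chao1", "shannon", "simpson", "goods_coverage")
BETA_METRICS = ("jaccard", "bray_curtis", "unweighted_unifrac",
                "weighted_unifrac")

__all__ = ["rarefy", "alpha", "alpha_table", "beta", "pcoa",
           "ALPHA_METRICS", "BETA_METRICS"]


def rarefy(table: FeatureTable, depth: int, seed: int,
           drop_empty_taxa: bool = True) -> FeatureTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped (logged), matching
    standard practice of rarefying to an even depth. A sample at exactly
    ``depth`` is returned unchanged.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    if not keep.any():
        raise ValueError(f"all samples below rarefaction depth {depth}")
    rows = []
    ids = []
    for sid, row, tot, k in zip(table.sample_ids, table.counts, totals, keep):
        if not k:
            continue
        ids.append(sid)
        if tot == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    out = FeatureTable(tuple(ids), table.taxon_ids,
                       np.asarray(rows, dtype=np.int64))
    return out.drop_empty_taxa() if drop_empty_taxa else out


def alpha(counts: Sequence[int] | np.ndarray, metric: str,
          chao1_variant: str = "classic", shannon_base: float = 2.0) -> float:
    """One alpha-diversity value for one sample's count vector.

    chao1 "classic" is S_obs + F1²/(2 F2), falling back to the
    bias-corrected S_obs + F1(F1−1)/(2(F2+1)) when F2 = 0; "bias_corrected"
    always uses the latter.
    """
    x = np.asarray(counts)
    if np.issubdtype(x.dtype, np.floating) and not np.allclose(x, np.rint(x)):
        raise ValueError("alpha metrics need integer counts")
    x = x.astype(np.int64)
    if (x < 0).any():
        raise ValueError("negative counts")
    x = x[x > 0]
    n = int(x.sum())
    if n == 0:
        raise ValueError("all-zero count vector: alpha metrics undefined")
    s_obs = len(x)
    if metric == "observed":
        return float(s_obs)
    if metric == "chao1":
        f1 = int((x == 1).sum())
        f2 = int((x == 2).sum())
        if chao1_variant == "bias_corrected" or f2 == 0:
            return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        if chao1_variant != "classic":
            raise ValueError(f"unknown chao1 variant {chao1_variant!r}")
        return s_obs + f1 * f1 / (2.0 * f2)
    p = x / n
    if metric == "shannon":
        return float(-(p * (np.log(p) / np.log(shannon_base))).sum())
    if metric == "simpson":
        return float(1.0 - (p * p).sum())
    if metric == "goods_coverage":
        return float(1.0 - (x == 1).sum() / n)
    raise ValueError(f"unknown alpha metric {metric!r}")


def alpha_table(table: FeatureTable, metrics: Sequence[str] = ALPHA_METRICS,
                **kwargs):
    """Alpha diversity for every sample; returns a samples × metrics frame."""
    import pandas as pd

    data = {m: [alpha(row, m, **kwargs) for row in table.counts]
            for m in metrics}
    return pd.DataFrame(data, index=list(table.sample_ids))


def _check_tree_covers(taxa, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise ValueError(
            f"{len(missing)} table taxa missing from tree: {missing[:10]}")


def _beta_impl(counts: np.ndarray, ids, taxa, metric: str,
               tree: TreeNode | None,
               normalized_unifrac: bool) -> DistanceMatrix:
    if metric == "jaccard":
        pres = (counts > 0).astype(float)
        vals = squareform(pdist(pres, metric="jaccard"), checks=False)
        return DistanceMatrix(vals, ids=ids)
    if metric == "bray_curtis":
        vals = squareform(pdist(counts.astype(float), metric="braycurtis"),
                          checks=False)
        return DistanceMatrix(vals, ids=ids)
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a microbial tree")
        _check_tree_covers(taxa, tree)
        kwargs = dict(taxa=list(taxa), tree=tree)
        if metric == "weighted_unifrac":
            kwargs["normalized"] = normalized_unifrac
        return _skbio_beta(metric, counts, ids=ids, validate=False, **kwargs)
    raise ValueError(f"unknown beta metric {metric!r}")


def beta(table: FeatureTable, metric: str,
         tree: TreeNode | None = None,
         normalized_unifrac: bool = False) -> DistanceMatrix:
    """Pairwise beta diversity between samples.

    jaccard: 1 − |A∩B| / |A∪B| on presence sets.
    bray_curtis: Σ|x−y| / Σ(x+y) on counts.
    unweighted_unifrac: fraction of observed branch length unique to one
    sample. weighted_unifrac: Σ_b len(b)·|p_A(b) − p_B(b)| (unnormalized by
    default; ``normalized_unifrac`` divides by the maximal attainable value).
    """
    return _beta_impl(table.counts, list(table.sample_ids),
                      table.taxon_ids, metric, tree, normalized_unifrac)


def beta_frame(frame, metric: str, tree: TreeNode | None = None,
               normalized_unifrac: bool = False) -> DistanceMatrix:
    """Beta diversity on a float abundance frame (rows = entities).

    Used for population-representative profiles, which are relative
    abundances rather than integer counts.
    """
    return _beta_impl(frame.to_numpy(dtype=float), list(frame.index),
                      list(frame.columns), metric, tree, normalized_unifrac)


def pcoa(dm: DistanceMatrix) -> OrdinationResults:
    """Classical scaling of the double-centered −½D² matrix.

    Axes with negative eigenvalues (non-Euclidean input) are dropped from
    the returned coordinates; eigenvalues are reported sorted descending.
    """
    if len(dm.ids) < 3:
        raise ValueError("PCoA needs at least 3 labels")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", dimensions=0,
                          warn_neg_eigval=False)
    pos = res.eigvals.to_numpy() > 1e-10
    res.samples = res.samples.loc[:, pos.tolist()]
    return res
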