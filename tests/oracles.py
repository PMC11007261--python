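"""Independent brute-force oracles used to validate the implementations.

Each oracle recomputes a statistic from its definition by direct
enumeration, staying deliberately independent of the code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def unifrac_unweighted_bruteforce(tree, presence_a: set[str],
                                  presence_b: set[str]) -> float:
    """Edge enumeration: unique observed branch length / total observed."""
    unique = total = 0.0
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} or {node.name}
        in_a = bool(leaves & presence_a)
        in_b = bool(leaves & presence_b)
        length = node.length or 0.0
        if in_a or in_b:
            total += length
            if in_a != in_b:
                unique += length
    return unique / total if total > 0 else 0.0


def rf_normalized_dendropy(newick1: str, newick2: str) -> float:
    """Robinson–Foulds via dendropy's bipartition machinery."""
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick",
                           taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick",
                           taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    rf = treecompare.symmetric_difference(t1, t2)
    n = len(tns)
    return rf / (2.0 * (n - 3))


def mantel_exhaustive(a: np.ndarray, b: np.ndarray,
                      method: str = "spearman"):
    """Observed statistic and exact p over all label permutations of a."""
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(x, y):
        if method == "spearman":
            return stats.spearmanr(x, y).statistic
        return stats.pearsonr(x, y).statistic

    obs = corr(a[iu], b[iu])
    count = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = corr(a[np.ix_(p, p)][iu], b[iu])
        total += 1
        if r >= obs - 1e-12:
            count += 1
    return obs, count / total


def permanova_f_definition(d: np.ndarray, codes: np.ndarray) -> float:
    """Pseudo-F from the sums-of-squares definition, straight loops."""
    n = len(codes)
    groups = sorted(set(codes))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        members = [i for i in range(n) if codes[i] == g]
        ng = len(members)
        ss_g = sum(d[i, j] ** 2 for i in members for j in members if i < j)
        ss_within += ss_g / ng
    ss_between = ss_total - ss_within
    df_b, df_w = len(groups) - 1, n - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def permanova_exhaustive(d: np.ndarray, codes: np.ndarray):
    """Exact permutation p for the pseudo-F over all label permutations."""
    obs = permanova_f_definition(d, codes)
    count = total = 0
    for perm in itertools.permutations(range(len(codes))):
        f = permanova_f_definition(d, codes[np.array(perm)])
        total += 1
        if f >= obs - 1e-12:
            count += 1
    return obs, count / total


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients from the normal equations (X'X) beta = X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)
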