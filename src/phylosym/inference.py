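"""Permutation statistics on distance matrices.

The inference stage asks which host covariates structure the microbiome:
Mantel and partial Mantel correlation between distance matrices, multiple
regression on distance matrices (MRM) with permutation inference,
PERMANOVA with pairwise post hocs, exhaustive step regression over
predictor subsets, a repeated-subsampling sensitivity protocol, and
rank-based group tests for alpha diversity.

All permutation p-values use the add-one convention
p = (#{permuted ≥ observed} + 1) / (n_perm + 1), so they lie in
[1/(n_perm+1), 1]. Exhaustive enumeration over all n! row/column
permutations is available for small matrices via ``exhaustive=True``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from phylosym.datamodel import FeatureTable, SampleMetadata
from phylosym.covariates import CovariateSet

__all__ = [
    "MantelResult", "MRMResult", "PermanovaResult", "SensitivityDistribution",
    "GroupTestReport", "mantel", "partial_mantel", "mrm", "permanova",
    "pairwise_permanova", "subsample_sensitivity", "step_regression",
    "group_tests",
]


# ------------------------------------------------------------- utilities
def _aligned_data(*dms: DistanceMatrix) -> list[np.ndarray]:
    ids = tuple(dms[0].ids)
    out = []
    for dm in dms:
        if tuple(dm.ids) != ids:
            if set(dm.ids) != set(ids):
                raise ValueError("distance matrices have different label sets")
            dm = dm.filter(list(ids))
        out.append(dm.data)
    return out


def _condense(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _refold(vec: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    return out + out.T


def _rank_offdiag(mat: np.ndarray) -> np.ndarray:
    """Rank-transform the unfolded entries, refolded to a symmetric matrix.

    Permuting rows/columns of a hollow symmetric matrix permutes the
    multiset of its off-diagonal entries, so ranking once and permuting the
    ranked matrix is equivalent to re-ranking after every permutation.
    """
    n = mat.shape[0]
    return _refold(stats.rankdata(_condense(mat)), n)


def _standardize(vec: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    sd = vec.std()
    if sd == 0:
        raise ValueError(f"degenerate statistic: {what} matrix is constant "
                         "over pairs")
    return (vec - vec.mean()) / sd, sd


def _perm_indices(n: int, n_perm: int, rng: np.random.Generator,
                  exhaustive: bool):
    if exhaustive:
        return [np.array(p) for p in itertools.permutations(range(n))]
    return [rng.permutation(n) for _ in range(n_perm)]


def _perm_pvalue(observed: float, permuted: np.ndarray,
                 exhaustive: bool) -> float:
    if exhaustive:
        # identity permutation is part of the enumeration
        return float((permuted >= observed - 1e-12).sum()) / len(permuted)
    return (float((permuted >= observed - 1e-12).sum()) + 1.0) / \
        (len(permuted) + 1.0)


# ---------------------------------------------------------------- Mantel
@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    controlled: tuple[str, ...] = ()


def mantel(a: DistanceMatrix, b: DistanceMatrix, method: str = "spearman",
           n_perm: int = 999, seed: int = 0, alternative: str = "greater",
           exhaustive: bool = False) -> MantelResult:
    """Mantel test of matrix correlation.

    The statistic is the (Spearman or Pearson) correlation of the unfolded
    upper-triangle entries; the null is generated by simultaneous
    row/column permutation of ``a``. One-sided (greater) by default, the
    convention of the ecology packages this mirrors.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if not exhaustive and n_perm < 99:
        raise ValueError("n_perm must be ≥ 99")
    A, B = _aligned_data(a, b)
    n = A.shape[0]
    Am = _rank_offdiag(A) if method == "spearman" else A
    bvec = _condense(B)
    if method == "spearman":
        bvec = stats.rankdata(bvec)
    zb, _ = _standardize(bvec, "second")
    avec = _condense(Am)
    za, _ = _standardize(avec, "first")
    m = len(za)
    r_obs = float(za @ zb) / m
    rng = np.random.default_rng(seed)
    perms = _perm_indices(n, n_perm, rng, exhaustive)
    # mean/sd of the unfolded vector are permutation-invariant
    mu, sd = avec.mean(), avec.std()
    permuted = np.empty(len(perms))
    for k, perm in enumerate(perms):
        x = _condense(Am[np.ix_(perm, perm)])
        permuted[k] = ((x - mu) / sd) @ zb / m
    stat = np.abs(permuted) if alternative == "two-sided" else permuted
    obs = abs(r_obs) if alternative == "two-sided" else r_obs
    p = _perm_pvalue(obs, stat, exhaustive)
    return MantelResult(r=r_obs, p=p, n_perm=len(perms), method=method)


def partial_mantel(a: DistanceMatrix, b: DistanceMatrix,
                   controls: Mapping[str, DistanceMatrix],
                   method: str = "spearman", n_perm: int = 999,
                   seed: int = 0, alternative: str = "greater") -> MantelResult:
    """Partial Mantel test via the residual method.

    The (rank-transformed, if Spearman) unfolded ``a`` and ``b`` vectors
    are each regressed on the unfolded control matrices; the Mantel
    statistic is the correlation of the two residual vectors, and the null
    permutes rows/columns of ``a``'s residuals refolded to a matrix.
    """
    if not controls:
        raise ValueError("no control matrices; use mantel() instead")
    if len(controls) > 3:
        raise ValueError("at most 3 control matrices supported")
    names = tuple(controls.keys())
    mats = _aligned_data(a, b, *controls.values())
    n = mats[0].shape[0]

    def unfold(mat: np.ndarray) -> np.ndarray:
        v = _condense(mat)
        return stats.rankdata(v) if method == "spearman" else v

    avec, bvec = unfold(mats[0]), unfold(mats[1])
    C = np.column_stack([np.ones(len(avec))] + [unfold(m) for m in mats[2:]])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        warnings.warn("collinear control matrices; partialling is "
                      "ill-conditioned", stacklevel=2)
    proj = C @ np.linalg.pinv(C)
    resid_a = avec - proj @ avec
    resid_b = bvec - proj @ bvec
    # controls explain a matrix completely: nothing left to correlate
    tol_a = 1e-10 * max(avec.std(), 1.0)
    tol_b = 1e-10 * max(bvec.std(), 1.0)
    if resid_a.std() < tol_a or resid_b.std() < tol_b:
        return MantelResult(r=0.0, p=1.0, n_perm=n_perm, method=method,
                            controlled=names)
    za, _ = _standardize(resid_a, "first residual")
    zb, _ = _standardize(resid_b, "second residual")
    m = len(za)
    r_obs = float(za @ zb) / m
    RA = _refold(resid_a, n)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    mu, sd = resid_a.mean(), resid_a.std()
    for k in range(n_perm):
        perm = rng.permutation(n)
        x = _condense(RA[np.ix_(perm, perm)])
        permuted[k] = ((x - mu) / sd) @ zb / m
    stat = np.abs(permuted) if alternative == "two-sided" else permuted
    obs = abs(r_obs) if alternative == "two-sided" else r_obs
    p = _perm_pvalue(obs, stat, False)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, method=method,
                        controlled=names)


# ------------------------------------------------------------------- MRM
@dataclass(frozen=True)
class MRMResult:
    coefficients: Mapping[str, float]
    r_squared: float
    p_r_squared: float
    coefficient_p: Mapping[str, float]
    n_perm: int


def mrm(response: DistanceMatrix, predictors: Mapping[str, DistanceMatrix],
        n_perm: int = 999, seed: int = 0) -> MRMResult:
    """Multiple regression on distance matrices.

    OLS of the unfolded response on the unfolded predictors; R² and
    coefficients are exact OLS, p-values come from permuting rows/columns
    of the response matrix and recomputing R² (one-sided) and |t| per
    coefficient (two-sided on the pseudo-t).
    """
    if not predictors:
        raise ValueError("at least one predictor required")
    names = list(predictors.keys())
    mats = _aligned_data(response, *predictors.values())
    n = mats[0].shape[0]
    y = _condense(mats[0])
    X = np.column_stack([np.ones_like(y)] + [_condense(m) for m in mats[1:]])
    m, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise np.linalg.LinAlgError(
            f"singular design: predictors {names} are collinear "
            f"(rank {rank} < {k})")
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T

    def fit(yv: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        beta = H @ yv
        resid = yv - X @ beta
        ss_res = resid @ resid
        ss_tot = ((yv - yv.mean()) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        dof = m - k
        sigma2 = ss_res / dof if dof > 0 else np.nan
        se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 1e-300))
        return beta, r2, np.abs(beta / se)

    beta_obs, r2_obs, t_obs = fit(y)
    Y = mats[0]
    rng = np.random.default_rng(seed)
    r2_perm = np.empty(n_perm)
    t_perm = np.empty((n_perm, k))
    for i in range(n_perm):
        perm = rng.permutation(n)
        _, r2_perm[i], t_perm[i] = fit(_condense(Y[np.ix_(perm, perm)]))
    p_r2 = _perm_pvalue(r2_obs, r2_perm, False)
    coef_p = {
        name: _perm_pvalue(t_obs[j + 1], t_perm[:, j + 1], False)
        for j, name in enumerate(names)
    }
    coefs = {"intercept": float(beta_obs[0])}
    coefs.update({name: float(beta_obs[j + 1]) for j, name in enumerate(names)})
    return MRMResult(coefficients=coefs, r_squared=float(r2_obs),
                     p_r_squared=p_r2, coefficient_p=coef_p, n_perm=n_perm)


# -------------------------------------------------------------- PERMANOVA
@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p: float
    n_perm: int
    groups: tuple[str, ...]
    p_adj: float | None = None


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        members = np.where(codes == g)[0]
        ng = len(members)
        ss_within += d2[np.ix_(members, members)].sum() / (2.0 * ng)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    with np.errstate(divide="ignore"):
        return (ss_between / df_between) / (ss_within / df_within)


def permanova(dm: DistanceMatrix, groups: Mapping[str, str],
              n_perm: int = 999, seed: int = 0,
              exhaustive: bool = False) -> PermanovaResult:
    """PERMANOVA pseudo-F with label-permutation p-value.

    Uses the Huygens decomposition: SS_total = Σ_{i<j} d²_ij / n and
    SS_within summed per group, with pseudo-F = (SS_b/df_b)/(SS_w/df_w).
    """
    labels = list(dm.ids)
    missing = [l for l in labels if l not in groups]
    if missing:
        raise ValueError(f"labels without group assignment: {missing}")
    cats = sorted({groups[l] for l in labels})
    if len(cats) < 2:
        raise ValueError("need at least 2 groups")
    codes = np.array([cats.index(groups[l]) for l in labels])
    sizes = np.bincount(codes, minlength=len(cats))
    small = [cats[i] for i in np.where(sizes < 2)[0]]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")
    d2 = dm.data ** 2
    f_obs = _pseudo_f(d2, codes, len(cats))
    rng = np.random.default_rng(seed)
    perms = _perm_indices(len(labels), n_perm, rng, exhaustive)
    f_perm = np.array([_pseudo_f(d2, codes[perm], len(cats))
                       for perm in perms])
    p = _perm_pvalue(f_obs, f_perm, exhaustive)
    return PermanovaResult(pseudo_f=float(f_obs), p=p, n_perm=len(perms),
                           groups=tuple(cats))


def pairwise_permanova(dm: DistanceMatrix, groups: Mapping[str, str],
                       n_perm: int = 999, seed: int = 0
                       ) -> list[PermanovaResult]:
    """All pairwise PERMANOVA comparisons, Benjamini–Hochberg adjusted."""
    labels = list(dm.ids)
    cats = sorted({groups[l] for l in labels})
    results = []
    rng = np.random.default_rng(seed)
    for g1, g2 in itertools.combinations(cats, 2):
        keep = [l for l in labels if groups[l] in (g1, g2)]
        sub = dm.filter(keep)
        res = permanova(sub, groups, n_perm=n_perm,
                        seed=int(rng.integers(2 ** 31)))
        results.append(res)
    if results:
        _, p_adj, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        results = [
            PermanovaResult(r.pseudo_f, r.p, r.n_perm, r.groups,
                            p_adj=float(max(pa, r.p)))
            for r, pa in zip(results, p_adj)
        ]
    return results


# -------------------------------------------------- subsample sensitivity
@dataclass(frozen=True)
class SensitivityDistribution:
    statistics: np.ndarray
    p_values: np.ndarray
    alpha_level: float
    test: str

    @property
    def significant_fraction(self) -> float:
        return float((self.p_values < self.alpha_level).mean())


def subsample_sensitivity(table: FeatureTable,
                          metadata: Sequence[SampleMetadata],
                          covariates: CovariateSet,
                          test: str = "partial_mantel",
                          metric: str = "bray_curtis",
                          tree=None,
                          n_subsamples: int = 100,
                          per_population: int = 3,
                          per_population_overrides: Mapping[str, int] | None = None,
                          focal: str = "genetics",
                          method: str = "spearman",
                          n_perm: int = 999,
                          alpha_level: float = 0.05,
                          seed: int = 0) -> SensitivityDistribution:
    """Repeated-subsampling sensitivity analysis.

    Each of ``n_subsamples`` iterations draws ``per_population`` samples
    (without replacement; per-population overrides allowed, as when one
    population contributes an extra sample) from every population,
    recomputes the beta-diversity matrix on the subsample, aligns the
    covariates, and reruns the chosen test (``partial_mantel`` of the focal
    covariate controlling the others, or full ``mrm``). Each iteration uses
    an independent seed stream derived from (seed, iteration), so the
    schedule is stable regardless of execution order.
    """
    from phylosym.diversity import beta as beta_fn

    if test not in ("partial_mantel", "mrm"):
        raise ValueError(f"unknown test {test!r}")
    overrides = dict(per_population_overrides or {})
    by_pop: dict[str, list[str]] = {}
    for m in metadata:
        by_pop.setdefault(m.population, []).append(m.sample_id)
    for pop, members in sorted(by_pop.items()):
        quota = overrides.get(pop, per_population)
        if len(members) < quota:
            raise ValueError(
                f"population {pop!r} has {len(members)} samples, fewer than "
                f"its quota {quota}")
    cov = covariates.as_dict()
    if focal not in cov:
        raise ValueError(f"focal covariate {focal!r} not in covariate set")
    stats_out = np.empty(n_subsamples)
    p_out = np.empty(n_subsamples)
    for i in range(n_subsamples):
        rng = np.random.default_rng([seed, i])
        chosen: list[str] = []
        for pop in sorted(by_pop):
            members = sorted(by_pop[pop])
            quota = overrides.get(pop, per_population)
            chosen.extend(rng.choice(members, size=quota, replace=False))
        sub = table.filter_samples(chosen).drop_empty_taxa()
        bdm = beta_fn(sub, metric, tree=tree)
        sub_cov = {k: v.filter(chosen) for k, v in cov.items()}
        test_seed = int(rng.integers(2 ** 31))
        if test == "partial_mantel":
            controls = {k: v for k, v in sub_cov.items() if k != focal}
            res = partial_mantel(bdm, sub_cov[focal], controls,
                                 method=method, n_perm=n_perm, seed=test_seed)
            stats_out[i], p_out[i] = res.r, res.p
        else:
            res = mrm(bdm, sub_cov, n_perm=n_perm, seed=test_seed)
            stats_out[i], p_out[i] = res.r_squared, res.p_r_squared
    return SensitivityDistribution(statistics=stats_out, p_values=p_out,
                                   alpha_level=alpha_level, test=test)


# --------------------------------------------------------- step regression
def step_regression(response: DistanceMatrix,
                    predictors: Mapping[str, DistanceMatrix],
                    n_perm: int = 999, seed: int = 0
                    ) -> dict[tuple[str, ...], MRMResult]:
    """MRM over every non-empty subset of predictors (step regression)."""
    names = list(predictors.keys())
    if len(names) > 6:
        raise ValueError("step regression limited to ≤ 6 predictors")
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, ...], MRMResult] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            sub = {k: predictors[k] for k in combo}
            out[combo] = mrm(response, sub, n_perm=n_perm,
                             seed=int(rng.integers(2 ** 31)))
    return out


# -------------------------------------------------------------- group tests
@dataclass(frozen=True)
class GroupTestReport:
    kruskal_h: float
    kruskal_p: float
    dunn_z: Mapping[tuple[str, str], float]
    dunn_p_adj: Mapping[tuple[str, str], float]
    groups: tuple[str, ...]


def _dunn_posthoc(values: np.ndarray, codes: np.ndarray,
                  cats: Sequence[str]):
    """Dunn's pairwise z statistics on pooled ranks, with tie correction."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_ranks = {g: ranks[codes == i].mean() for i, g in enumerate(cats)}
    sizes = {g: int((codes == i).sum()) for i, g in enumerate(cats)}
    zs, raw_p, pairs = {}, [], []
    for g1, g2 in itertools.combinations(cats, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) *
                     (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        zs[(g1, g2)] = float(z)
        raw_p.append(2.0 * stats.norm.sf(abs(z)))
        pairs.append((g1, g2))
    if raw_p:
        _, p_adj, _, _ = multipletests(raw_p, method="fdr_bh")
    else:
        p_adj = []
    return zs, dict(zip(pairs, map(float, p_adj)))


def group_tests(values: Mapping[str, float],
                groups: Mapping[str, str]) -> GroupTestReport:
    """Kruskal–Wallis with Dunn's post hoc (Benjamini–Hochberg adjusted).

    All-tied values give a degenerate-test warning and p = 1.
    """
    labels = list(values.keys())
    missing = [l for l in labels if l not in groups]
    if missing:
        raise ValueError(f"values without group assignment: {missing}")
    cats = sorted({groups[l] for l in labels})
    if len(cats) < 2:
        raise ValueError("need at least 2 groups")
    codes = np.array([cats.index(groups[l]) for l in labels])
    sizes = np.bincount(codes, minlength=len(cats))
    small = [cats[i] for i in np.where(sizes < 2)[0]]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")
    vals = np.array([values[l] for l in labels], dtype=float)
    if np.ptp(vals) == 0:
        warnings.warn("all values tied; group tests degenerate",
                      stacklevel=2)
        zeros = {pair: 0.0 for pair in itertools.combinations(cats, 2)}
        ones = {pair: 1.0 for pair in itertools.combinations(cats, 2)}
        return GroupTestReport(0.0, 1.0, zeros, ones, tuple(cats))
    samples = [vals[codes == i] for i in range(len(cats))]
    h, p = stats.kruskal(*samples)
    dunn_z, dunn_p = _dunn_posthoc(vals, codes, cats)
    return GroupTestReport(float(h), float(p), dunn_z, dunn_p, tuple(cats))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann–Whitney) for comparing statistic
    distributions, e.g. partial Mantel r across taxonomic levels."""
    res = stats.mannwhitneyu(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
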