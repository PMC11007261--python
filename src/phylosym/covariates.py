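"""Explanatory distance matrices for host covariates.

Four matrices drive the inference stage: host genetic distance (Kimura
2-parameter, optionally gamma-corrected), great-circle geographic distance,
and Gower distances for diet (host plant) and altitude. Alpha-diversity
values can additionally be turned into 1-D Euclidean matrices so that alpha
diversity itself can serve as a response in matrix regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix

from phylosym.datamodel import AlignedSequences, SampleMetadata

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

__all__ = [
    "CovariateSet", "k2p_distance", "great_circle_matrix", "gower_matrix",
    "alpha_euclidean", "expand_to_samples", "EARTH_RADIUS_KM",
    "SaturationError", "covariates_from_metadata",
]


class SaturationError(ValueError):
    """K2P distance undefined: too many substitutions between a pair."""


@dataclass(frozen=True)
class CovariateSet:
    """The four explanatory matrices, aligned to one label set."""

    genetics: DistanceMatrix
    geography: DistanceMatrix
    altitude: DistanceMatrix
    host_plant: DistanceMatrix

    def __post_init__(self) -> None:
        ids = self.genetics.ids
        for name in ("geography", "altitude", "host_plant"):
            other = getattr(self, name).ids
            if tuple(other) != tuple(ids):
                raise ValueError(
                    f"covariate {name!r} labels differ from genetics labels")

    def as_dict(self) -> dict[str, DistanceMatrix]:
        return {"genetics": self.genetics, "geography": self.geography,
                "altitude": self.altitude, "host_plant": self.host_plant}


def _k2p_pq(a: str, b: str) -> tuple[float, float]:
    """Transition/transversion proportions with pairwise gap/N deletion."""
    transitions = transversions = valid = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        valid += 1
        if x == y:
            continue
        if (x in _PURINES and y in _PURINES) or \
           (x in _PYRIMIDINES and y in _PYRIMIDINES):
            transitions += 1
        else:
            transversions += 1
    if valid == 0:
        raise ValueError("no comparable (ungapped) sites between sequences")
    return transitions / valid, transversions / valid


def k2p_pair(p: float, q: float, gamma_shape: float | None = None) -> float:
    """Kimura 2-parameter distance from transition/transversion proportions.

    Without gamma: d = −½ ln(1−2P−Q) − ¼ ln(1−2Q). With gamma shape a, the
    Jin–Nei rate-heterogeneity correction:
    d = (a/2)[(1−2P−Q)^(−1/a) − 1] + (a/4)[(1−2Q)^(−1/a) − 1].
    """
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair: P={p:.4f}, Q={q:.4f} leave log arguments ≤ 0")
    if gamma_shape is None:
        return -0.5 * np.log(w1) - 0.25 * np.log(w2)
    a = float(gamma_shape)
    if a <= 0:
        raise ValueError("gamma shape must be positive")
    return (a / 2.0) * (w1 ** (-1.0 / a) - 1.0) + \
           (a / 4.0) * (w2 ** (-1.0 / a) - 1.0)


def k2p_distance(aln: AlignedSequences,
                 gamma_shape: float | None = None) -> DistanceMatrix:
    """Pairwise K2P(+gamma) distances over an alignment.

    Sites with gaps or N are excluded pairwise. A saturated pair (log
    argument ≤ 0) raises :class:`SaturationError` naming the pair rather
    than clamping, since clamped values would distort downstream Mantel
    ranks.
    """
    n = len(aln)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, q = _k2p_pq(aln.sequences[i], aln.sequences[j])
            try:
                d = k2p_pair(p, q, gamma_shape)
            except SaturationError as exc:
                raise SaturationError(
                    f"pair ({aln.labels[i]!r}, {aln.labels[j]!r}): {exc}"
                ) from exc
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids=list(aln.labels))


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of mean Earth radius."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1))))


def great_circle_matrix(metadata: Sequence[SampleMetadata]) -> DistanceMatrix:
    """Pairwise great-circle (haversine) distances between sampling sites."""
    labels = [m.sample_id for m in metadata]
    lat = np.array([m.latitude for m in metadata])
    lon = np.array([m.longitude for m in metadata])
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(out, ids=labels)


def gower_matrix(values: Mapping[str, float | str]) -> DistanceMatrix:
    """Single-column Gower dissimilarity.

    Numeric: |x − y| / range (all-zero if the range is 0). Categorical:
    0/1 mismatch. Mixed numeric and string values are a type error.
    """
    labels = list(values.keys())
    vals = list(values.values())
    if len(labels) < 2:
        raise ValueError("need at least 2 entities")
    numeric = [isinstance(v, (int, float, np.integer, np.floating))
               and not isinstance(v, bool) for v in vals]
    if all(numeric):
        x = np.array(vals, dtype=float)
        rng = x.max() - x.min()
        if rng == 0:
            out = np.zeros((len(x), len(x)))
        else:
            out = np.abs(x[:, None] - x[None, :]) / rng
    elif not any(numeric):
        x = np.array([str(v) for v in vals], dtype=object)
        out = (x[:, None] != x[None, :]).astype(float)
    else:
        raise TypeError("mixed numeric and categorical values in one column")
    return DistanceMatrix(out, ids=labels)


def alpha_euclidean(alpha_values: Mapping[str, float]) -> DistanceMatrix:
    """1-D Euclidean distance |a_i − a_j| between per-sample alpha values."""
    labels = list(alpha_values.keys())
    x = np.array(list(alpha_values.values()), dtype=float)
    if not np.isfinite(x).all():
        bad = [labels[i] for i in np.where(~np.isfinite(x))[0]]
        raise ValueError(f"non-finite alpha values for: {bad}")
    out = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(out, ids=labels)


def expand_to_samples(population_dm: DistanceMatrix,
                      sample_to_population: Mapping[str, str]) -> DistanceMatrix:
    """Lift a population-level matrix to sample level.

    d(s, t) = distance between the samples' populations; 0 for
    same-population pairs. Host genetics is typically measured per
    population while the microbiome is measured per sample, so this aligns
    the two resolutions.
    """
    pops = set(population_dm.ids)
    unmapped = [s for s, p in sample_to_population.items() if p not in pops]
    if unmapped:
        raise KeyError(
            f"samples map to populations absent from matrix: {unmapped}")
    samples = list(sample_to_population.keys())
    idx = {p: i for i, p in enumerate(population_dm.ids)}
    rows = np.array([idx[sample_to_population[s]] for s in samples])
    out = population_dm.data[np.ix_(rows, rows)].copy()
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(out, ids=samples)


def covariates_from_metadata(metadata: Sequence[SampleMetadata],
                             genetics: DistanceMatrix) -> CovariateSet:
    """Assemble a CovariateSet at sample level from metadata + genetics.

    ``genetics`` may be population-level (expanded via the metadata
    mapping) or already sample-level.
    """
    sample_ids = [m.sample_id for m in metadata]
    mapping = {m.sample_id: m.population for m in metadata}
    if set(genetics.ids) == set(sample_ids):
        gen = genetics.filter(sample_ids)
    else:
        gen = expand_to_samples(genetics, mapping)
    geo = great_circle_matrix(metadata)
    alt = gower_matrix({m.sample_id: float(m.altitude) for m in metadata})
    plant = gower_matrix({m.sample_id: m.host_plant for m in metadata})
    return CovariateSet(genetics=gen, geography=geo.filter(sample_ids),
                        altitude=alt.filter(sample_ids),
                        host_plant=plant.filter(sample_ids))
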