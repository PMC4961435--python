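"""Pairwise beta-diversity partition and predictor distance matrices.

Total compositional beta-diversity between two sites is the Jaccard
dissimilarity

    beta_cc = (b + c) / (a + b + c)

where ``a`` counts species shared by both sites and ``b``, ``c`` count
species exclusive to the first and second site.  beta_cc decomposes
additively into a species-richness-difference component and a
species-replacement component:

    beta_rich = |b - c| / (a + b + c)
    beta_3    = 2 * min(b, c) / (a + b + c)
    beta_cc   = beta_rich + beta_3

min(b, c) is the number of species substitutions between the two sites;
the factor 2 appears because each substitution involves two species.
The additivity is exact and is enforced as an invariant.

The module also builds every predictor matrix the regression stage uses:
Bray-Curtis dissimilarity on forest-type abundances, absolute differences
of per-site scalars (optionally log-transformed, e.g. import value and
forest area), and great-circle distances between site centroids.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_io import (
    CommunityMatrix,
    DistanceMatrix,
    DomainError,
    ModeError,
    SiteAttributes,
    UndefinedPairError,
    ValueValidationError,
)

__all__ = [
    "PairComposition",
    "BetaPartition",
    "pair_composition",
    "beta_partition_pair",
    "beta_partition_matrix",
    "bray_curtis_matrix",
    "scalar_distance_matrix",
    "haversine_matrix",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0


class PairComposition(NamedTuple):
    """Shared / exclusive species counts for one pair of sites."""

    a: int  # shared
    b: int  # exclusive to first site
    c: int  # exclusive to second site


def pair_composition(x: Sequence[float], y: Sequence[float]) -> PairComposition:
    """Count shared and exclusive species between two incidence rows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueValidationError("incidence rows must be 1-D and equal length")
    for v in (x, y):
        if not np.all(np.isin(v, (0.0, 1.0))):
            raise ModeError("pair_composition requires strict 0/1 incidence rows")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    return PairComposition(a, b, c)


def beta_partition_pair(pc: PairComposition) -> tuple[float, float, float]:
    """(beta_cc, beta_rich, beta_3) for one pair of communities."""
    a, b, c = pc
    if min(a, b, c) < 0:
        raise ValueValidationError("a, b, c must be nonnegative")
    tot = a + b + c
    if tot == 0:
        raise UndefinedPairError("both communities empty: a+b+c = 0")
    beta_cc = (b + c) / tot
    beta_rich = abs(b - c) / tot
    beta_3 = 2.0 * min(b, c) / tot
    return beta_cc, beta_rich, beta_3


@dataclass
class BetaPartition:
    """The three matrices of the partition plus the study's summary means."""

    beta_cc: DistanceMatrix
    beta_rich: DistanceMatrix
    beta_3: DistanceMatrix

    def __post_init__(self) -> None:
        self.beta_cc.require_same_labels(self.beta_rich)
        self.beta_cc.require_same_labels(self.beta_3)
        resid = self.beta_cc.d - (self.beta_rich.d + self.beta_3.d)
        if np.max(np.abs(resid)) > 1e-12:
            raise ValueValidationError("additivity beta_cc = beta_rich + beta_3 violated")
        for m in (self.beta_cc, self.beta_rich, self.beta_3):
            if np.any(m.d < 0) or np.any(m.d > 1):
                raise ValueValidationError("beta components must lie in [0, 1]")

    @property
    def mean_beta_rich(self) -> float:
        """Mean off-diagonal richness-difference component."""
        return float(self.beta_rich.condensed().mean())

    @property
    def mean_beta_3(self) -> float:
        """Mean off-diagonal replacement component."""
        return float(self.beta_3.condensed().mean())


def beta_partition_matrix(cm: CommunityMatrix) -> BetaPartition:
    """Partition beta-diversity over all site pairs of an incidence matrix.

    Vectorised via the incidence cross-product: A = X X', b_ij = r_i - a_ij,
    c_ij = r_j - a_ij with r the site richness vector.
    """
    if cm.mode != "incidence":
        raise ModeError("beta partition requires an incidence matrix")
    if cm.n_sites < 2:
        raise ValueValidationError("need at least 2 sites")
    X = cm.values
    A = X @ X.T
    r = X.sum(axis=1)
    B = r[:, None] - A
    C = r[None, :] - A
    tot = A + B + C
    iu = np.triu_indices(cm.n_sites, k=1)
    bad = np.argwhere(tot == 0)
    bad = bad[bad[:, 0] < bad[:, 1]]
    if bad.size:
        i, j = bad[0]
        raise UndefinedPairError(
            f"both communities empty for pair ({cm.site_ids[i]!r}, {cm.site_ids[j]!r})"
        )
    with np.errstate(invalid="ignore"):
        cc = (B + C) / tot
        rich = np.abs(B - C) / tot
        rep = 2.0 * np.minimum(B, C) / tot
    for m in (cc, rich, rep):
        np.fill_diagonal(m, 0.0)
    labels = list(cm.site_ids)
    return BetaPartition(
        beta_cc=DistanceMatrix(labels, cc),
        beta_rich=DistanceMatrix(labels, rich),
        beta_3=DistanceMatrix(labels, rep),
    )


def bray_curtis_matrix(cm: CommunityMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) on abundances."""
    if np.any(cm.values < 0):
        raise ValueValidationError("Bray-Curtis requires nonnegative abundances")
    zero = np.flatnonzero(cm.values.sum(axis=1) == 0)
    if zero.size >= 2:
        i, j = zero[:2]
        raise UndefinedPairError(
            f"all-zero pair ({cm.site_ids[i]!r}, {cm.site_ids[j]!r}): "
            "Bray-Curtis undefined"
        )
    if zero.size == 1 and cm.n_sites < 2:
        raise ValueValidationError("need at least 2 sites")
    d = squareform(pdist(cm.values, metric="braycurtis"))
    return DistanceMatrix(list(cm.site_ids), d)


def scalar_distance_matrix(
    values: Sequence[float],
    labels: Sequence[str],
    transform: str = "none",
) -> DistanceMatrix:
    """Pairwise absolute differences of a per-site scalar.

    ``transform="log"`` applies the natural log first (used for import
    value and forest cover area); it requires strictly positive values.
    """
    v = np.asarray(values, dtype=float)
    if transform == "log":
        if np.any(v <= 0):
            raise DomainError("log transform requires strictly positive values")
        v = np.log(v)
    elif transform != "none":
        raise DomainError(f"unknown transform {transform!r}")
    d = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(list(labels), d)


def haversine_matrix(attrs: SiteAttributes) -> DistanceMatrix:
    """Great-circle distances (km) between site centroids.

    Spherical haversine with R = 6371 km; state-centroid scale tolerates
    the sphere-vs-ellipsoid error.
    """
    lat = np.radians(attrs.column("lat"))
    lon = np.radians(attrs.column("lon"))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # kill rounding asymmetry
    return DistanceMatrix(attrs.site_ids, d)
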