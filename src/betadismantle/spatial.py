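"""Mantel statistics and distance-class correlograms.

A Mantel correlogram profiles spatial autocorrelation of a community
dissimilarity matrix: geographic pair distances are binned into
equal-width classes, and for each class the Mantel correlation between
the response matrix and the class-membership indicator is computed and
tested by permuting site order.  Because the response is a
*dissimilarity*, the reported statistic is sign-flipped so that a
positive value means "pairs in this class are more similar than
expected by chance" (and negative means increased dissimilarity) —
the convention under which correlogram figures are usually read.

Significance across classes uses the progressive Bonferroni rule: the
i-th class in order of increasing distance is tested at alpha / i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import DegenerateMatrixError, DistanceMatrix, DomainError

__all__ = [
    "MantelTestResult",
    "CorrelogramResult",
    "mantel_r",
    "mantel_permutation_test",
    "sturges_class_count",
    "mantel_correlogram",
]


def _condensed_checked(dm: DistanceMatrix, name: str) -> np.ndarray:
    v = dm.condensed()
    if np.ptp(v) == 0:
        raise DegenerateMatrixError(f"{name} is constant off-diagonal")
    return v


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def mantel_r(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Pearson correlation of the unfolded upper triangles of two matrices."""
    d1.require_same_labels(d2)
    return _pearson(_condensed_checked(d1, "d1"), _condensed_checked(d2, "d2"))


@dataclass
class MantelTestResult:
    r: float
    p_value: float
    n_perm: int
    alternative: str


def permuted_condensed(
    d: np.ndarray, perms: np.ndarray, chunk: int = 512
) -> np.ndarray:
    """Upper triangles of d under each joint row/column permutation.

    Batched fancy indexing, chunked to bound memory at
    ``chunk * n * n`` floats; returns an (n_perm, n(n-1)/2) array.
    """
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    out = np.empty((perms.shape[0], iu[0].size))
    for lo in range(0, perms.shape[0], chunk):
        p = perms[lo : lo + chunk]
        out[lo : lo + chunk] = d[p[:, :, None], p[:, None, :]][:, iu[0], iu[1]]
    return out


def mantel_permutation_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    alternative: str = "two-sided",
    seed: int | np.random.Generator | None = None,
) -> MantelTestResult:
    """Mantel test permuting the site order of ``d2`` jointly over rows and
    columns.  p = (1 + #extreme) / (1 + n_perm); the site, not the pair, is
    the exchangeable unit.
    """
    if n_perm < 99:
        raise DomainError("n_perm must be >= 99")
    if alternative not in ("two-sided", "greater", "less"):
        raise DomainError(f"unknown alternative {alternative!r}")
    d1.require_same_labels(d2)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    x = _condensed_checked(d1, "d1")
    _condensed_checked(d2, "d2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    xc = x - x.mean()
    xnorm = math.sqrt(xc @ xc)

    def corr_with_x(rows: np.ndarray) -> np.ndarray:
        yc = rows - rows.mean(axis=1, keepdims=True)
        denom = xnorm * np.sqrt(np.einsum("ij,ij->i", yc, yc))
        return (yc @ xc) / denom

    r_obs = _pearson(x, d2.condensed())
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    r_perm = corr_with_x(permuted_condensed(d2.d, perms))

    if alternative == "two-sided":
        extreme = np.abs(r_perm) >= abs(r_obs) - 1e-15
    elif alternative == "greater":
        extreme = r_perm >= r_obs - 1e-15
    else:
        extreme = r_perm <= r_obs + 1e-15
    p = (1 + int(extreme.sum())) / (1 + n_perm)
    return MantelTestResult(r=r_obs, p_value=p, n_perm=n_perm, alternative=alternative)


def sturges_class_count(n_pairs: int) -> int:
    """Number of distance classes by Sturges' rule: ceil(1 + log2(n_pairs))."""
    if n_pairs < 1:
        raise DomainError("n_pairs must be >= 1")
    return math.ceil(1.0 + math.log2(n_pairs))


@dataclass
class CorrelogramResult:
    """Per-distance-class Mantel statistics.

    ``table`` columns: class_index (1..k by increasing distance), lo, hi,
    midpoint, n_pairs, mantel_r, p_value, bonferroni_threshold, significant.
    Untestable classes (fewer than 2 member pairs) report r where defined
    and NaN p.  ``sign_convention`` records whether the similarity-positive
    flip was applied.
    """

    table: pd.DataFrame
    alpha: float
    n_perm: int
    sign_convention: str = "similarity-positive"

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def mantel_correlogram(
    d_resp: DistanceMatrix,
    d_geo: DistanceMatrix,
    n_classes: int | None = None,
    n_perm: int = 999,
    alpha: float = 0.05,
    sign_convention: str = "similarity-positive",
    seed: int | np.random.Generator | None = None,
) -> CorrelogramResult:
    """Mantel correlogram of a dissimilarity matrix against geographic distance.

    Classes are equal-width over [min, max] of the off-diagonal geographic
    distances, half-open [lo, hi) with the last class closed.  For class i
    the statistic is the Mantel correlation between ``d_resp`` and the 0/1
    within-class indicator matrix, sign-flipped (under the default
    convention) so positive = within-class pairs more similar than chance.
    Permutations shuffle the site order of the response matrix only.
    """
    d_resp.require_same_labels(d_geo)
    if sign_convention not in ("similarity-positive", "raw"):
        raise DomainError(f"unknown sign_convention {sign_convention!r}")
    n = d_resp.n
    iu = np.triu_indices(n, k=1)
    g = d_geo.condensed()
    y = _condensed_checked(d_resp, "d_resp")
    if np.ptp(g) == 0:
        raise DegenerateMatrixError("geographic matrix is constant off-diagonal")

    if n_classes is None:
        n_classes = sturges_class_count(g.size)
    if n_classes < 2:
        raise DomainError("n_classes must be >= 2 (or None for Sturges)")

    edges = np.linspace(g.min(), g.max(), n_classes + 1)
    # class index per pair: half-open bins, last closed
    cls = np.minimum(np.searchsorted(edges, g, side="right") - 1, n_classes - 1)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flip = -1.0 if sign_convention == "similarity-positive" else 1.0

    indicators = np.zeros((n_classes, g.size))
    for i in range(n_classes):
        indicators[i, cls == i] = 1.0
    counts = indicators.sum(axis=1).astype(int)
    testable = counts >= 2

    # centred/normalised indicator rows for fast correlation with permuted y
    ic = indicators - indicators.mean(axis=1, keepdims=True)
    inorm = np.sqrt(np.einsum("ij,ij->i", ic, ic))

    def class_corrs(yvec: np.ndarray) -> np.ndarray:
        yc = yvec - yvec.mean()
        ynorm = math.sqrt(yc @ yc)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (ic @ yc) / (inorm * ynorm)

    r_obs = flip * class_corrs(y)

    p = np.full(n_classes, np.nan)
    if n_perm >= 1:
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        Y = permuted_condensed(d_resp.d, perms)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        ynorms = np.sqrt(np.einsum("ij,ij->i", Yc, Yc))
        with np.errstate(invalid="ignore", divide="ignore"):
            rp = flip * (Yc @ ic.T) / (ynorms[:, None] * inorm[None, :])
        exceed = (np.abs(rp) >= np.abs(r_obs)[None, :] - 1e-15).sum(axis=0)
        p_all = (1 + exceed) / (1 + n_perm)
        p[testable] = p_all[testable]

    idx = np.arange(1, n_classes + 1)
    thresh = alpha / idx
    significant = np.where(np.isnan(p), False, p <= thresh)

    table = pd.DataFrame(
        {
            "class_index": idx,
            "lo": edges[:-1],
            "hi": edges[1:],
            "midpoint": (edges[:-1] + edges[1:]) / 2.0,
            "n_pairs": counts,
            "mantel_r": r_obs,
            "p_value": p,
            "bonferroni_threshold": thresh,
            "significant": significant,
        }
    )
    return CorrelogramResult(
        table=table, alpha=alpha, n_perm=n_perm, sign_convention=sign_convention
    )
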