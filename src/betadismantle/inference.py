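"""Multiple regression on distance matrices (MRM) and hierarchical
partitioning of explained variation.

MRM regresses the unfolded upper triangle of a response distance matrix
on the unfolded triangles of predictor matrices by ordinary least
squares.  Because matrix entries are not independent, coefficient
inference permutes the *site* order (rows and columns jointly) of the
response matrix — pairs are not exchangeable, sites are.  Predictor
matrices are standardized (off-diagonal mean 0, SD 1) before fitting;
quadratic terms are elementwise squares of the standardized matrices and
are not re-standardized.

Hierarchical partitioning averages, over all 2^k predictor subsets, the
R² gain each predictor contributes when added to a subset, with the
standard hierarchy-level weights (equivalently the Shapley value of R²).
The independent contributions sum exactly to the full-model R²; the
joint contribution of predictor k is its marginal R² minus its
independent contribution and may be negative (suppression).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    CollinearityError,
    DegenerateMatrixError,
    DistanceMatrix,
    DomainError,
    LabelError,
)
from .spatial import permuted_condensed

__all__ = [
    "MRMResult",
    "HPResult",
    "standardize_distance_matrix",
    "mrm_fit",
    "mrm_table",
    "hierarchical_partition",
]


def standardize_distance_matrix(d: DistanceMatrix) -> DistanceMatrix:
    """Center and scale the off-diagonal entries to mean 0, SD 1 (ddof=1).

    The diagonal stays 0.  The result is a regressor, not a metric, so
    negative entries are allowed.  Idempotent.
    """
    v = d.condensed()
    sd = v.std(ddof=1)
    if sd == 0 or np.ptp(v) == 0:
        raise DegenerateMatrixError("cannot standardize a constant matrix")
    z = (d.d - v.mean()) / sd
    np.fill_diagonal(z, 0.0)
    return DistanceMatrix(list(d.labels), z, allow_negative=True)


def _design(
    predictors: dict[str, DistanceMatrix],
    quadratic_for: tuple[str, ...],
    labels: list[str],
) -> tuple[list[str], np.ndarray]:
    """Standardize predictors and unfold to a design matrix with intercept."""
    names: list[str] = ["(intercept)"]
    n = len(labels)
    m = n * (n - 1) // 2
    cols = [np.ones(m)]
    for name, dm in predictors.items():
        if dm.labels != labels:
            raise LabelError(f"predictor {name!r} has mismatched site labels")
        z = standardize_distance_matrix(dm).condensed()
        names.append(name)
        cols.append(z)
        if name in quadratic_for:
            names.append(f"{name}^2")
            cols.append(z**2)
    unknown = set(quadratic_for) - set(predictors)
    if unknown:
        raise DomainError(f"quadratic_for names not among predictors: {sorted(unknown)}")
    X = np.column_stack(cols)
    # incremental rank check to name the offending term
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            raise CollinearityError(f"term {names[j]!r} is collinear with earlier terms")
        rank = new_rank
    return names, X


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss
    return beta, r2


@dataclass
class MRMResult:
    """Coefficients on standardized predictor matrices with permutation p."""

    terms: pd.DataFrame  # columns: term, coefficient, p_value
    r_squared: float
    n_perm: int
    seed: int | None

    def coefficient(self, term: str) -> float:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["coefficient"].iloc[0])

    def p_value(self, term: str) -> float:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["p_value"].iloc[0])


def mrm_fit(
    response: DistanceMatrix,
    predictors: dict[str, DistanceMatrix],
    quadratic_for: tuple[str, ...] = (),
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> MRMResult:
    """Fit MRM and test each coefficient by site permutation of the response.

    p = (1 + #{|b_perm| >= |b_obs|}) / (1 + n_perm) per term (intercept
    excluded from testing but reported).
    """
    if n_perm < 99:
        raise DomainError("n_perm must be >= 99")
    if not predictors:
        raise DomainError("at least one predictor required")
    labels = list(response.labels)
    names, X = _design(predictors, tuple(quadratic_for), labels)
    y = response.condensed()
    if np.ptp(y) == 0:
        raise DegenerateMatrixError("response matrix is constant off-diagonal")

    beta, r2 = _ols_r2(X, y)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = response.n
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Y = permuted_condensed(response.d, perms)
    pinv = np.linalg.pinv(X)
    B = Y @ pinv.T  # (n_perm, n_terms)
    exceed = (np.abs(B) >= np.abs(beta)[None, :] - 1e-15).sum(axis=0)
    pvals = (1 + exceed) / (1 + n_perm)
    pvals[0] = np.nan  # intercept not tested

    terms = pd.DataFrame({"term": names, "coefficient": beta, "p_value": pvals})
    seed_out = seed if isinstance(seed, int) else None
    return MRMResult(terms=terms, r_squared=r2, n_perm=n_perm, seed=seed_out)


def mrm_table(
    response: DistanceMatrix,
    predictors: dict[str, DistanceMatrix],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    quadratic_p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-predictor MRM summary in the shape of the study's regression table.

    For each predictor, fit the linear model, then linear + quadratic; the
    quadratic term is retained only when its permutation p-value falls
    below ``quadratic_p_threshold``.  Rows: predictor and (if retained)
    predictor², with coefficient, p and cumulative R² (linear alone vs
    linear plus quadratic).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for name, dm in predictors.items():
        lin = mrm_fit(response, {name: dm}, n_perm=n_perm, seed=rng)
        quad = mrm_fit(response, {name: dm}, quadratic_for=(name,), n_perm=n_perm, seed=rng)
        keep_quad = quad.p_value(f"{name}^2") < quadratic_p_threshold
        model = quad if keep_quad else lin
        rows.append(
            {
                "term": name,
                "coefficient": model.coefficient(name),
                "p_value": model.p_value(name),
                "r_squared": model.r_squared,
            }
        )
        if keep_quad:
            rows.append(
                {
                    "term": f"{name}^2",
                    "coefficient": model.coefficient(f"{name}^2"),
                    "p_value": model.p_value(f"{name}^2"),
                    "r_squared": model.r_squared,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class HPResult:
    """Independent / joint R² decomposition per predictor."""

    table: pd.DataFrame  # columns: predictor, independent, joint, total
    full_r_squared: float

    def independent(self, name: str) -> float:
        return float(self.table.set_index("predictor").loc[name, "independent"])

    def joint(self, name: str) -> float:
        return float(self.table.set_index("predictor").loc[name, "joint"])

    @property
    def top_independent(self) -> str:
        t = self.table
        return str(t.loc[t["independent"].idxmax(), "predictor"])


def hierarchical_partition(
    response: DistanceMatrix,
    predictors: dict[str, DistanceMatrix],
) -> HPResult:
    """Hierarchical partitioning of R² over all predictor subsets.

    I_k = sum over subsets S not containing k of
          w(|S|) * [R²(S ∪ {k}) − R²(S)],  w(s) = s!(p−s−1)!/p!
    J_k = R²({k}) − I_k.  Linear terms only; R² is OLS on unfolded
    upper triangles of standardized predictor matrices.
    """
    p = len(predictors)
    if p < 1:
        raise DomainError("at least one predictor required")
    if p > 12:
        raise DomainError("hierarchical partitioning limited to 12 predictors (2^k subsets)")
    labels = list(response.labels)
    names = list(predictors)
    cols = {}
    for name, dm in predictors.items():
        if dm.labels != labels:
            raise LabelError(f"predictor {name!r} has mismatched site labels")
        cols[name] = standardize_distance_matrix(dm).condensed()
    y = response.condensed()
    if np.ptp(y) == 0:
        raise DegenerateMatrixError("response matrix is constant off-diagonal")
    ones = np.ones_like(y)

    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}
    # R² is well-defined even for collinear subsets (lstsq projects onto the
    # column space), so identical predictors legitimately split their shared
    # variance instead of raising.
    for r in range(1, p + 1):
        for S in itertools.combinations(names, r):
            X = np.column_stack([ones] + [cols[s] for s in S])
            _, r2 = _ols_r2(X, y)
            r2_cache[frozenset(S)] = r2

    fact = [math.factorial(i) for i in range(p + 1)]
    rows = []
    for k in names:
        others = [n_ for n_ in names if n_ != k]
        I = 0.0
        for r in range(0, p):
            w = fact[r] * fact[p - r - 1] / fact[p]
            for S in itertools.combinations(others, r):
                S = frozenset(S)
                I += w * (r2_cache[S | {k}] - r2_cache[S])
        marginal = r2_cache[frozenset({k})]
        rows.append(
            {"predictor": k, "independent": I, "joint": marginal - I, "total": marginal}
        )
    full = r2_cache[frozenset(names)]
    return HPResult(table=pd.DataFrame(rows), full_r_squared=full)
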