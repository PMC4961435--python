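"""Non-metric multidimensional scaling of a dissimilarity matrix.

NMDS embeds sites in k dimensions so that configuration distances are
monotonically related to the input dissimilarities, minimising Kruskal
stress-1 = sqrt(sum (d_hat - f(d))^2 / sum d_hat^2) with f the isotonic
regression of configuration distances on input dissimilarities (Kruskal
primary tie treatment: tied inputs may receive equal fitted values).

The optimiser is non-metric SMACOF (scikit-learn's implementation).  The
first start is classical metric scaling of the input — a deterministic,
usually excellent initial configuration — and remaining starts are
seeded random configurations; the best stress wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.manifold import smacof

from .core_io import DegenerateMatrixError, DistanceMatrix, DomainError

__all__ = ["NMDSResult", "nmds", "classical_scaling"]


def classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling: eigendecomposition of the doubly
    centred squared-distance matrix, top-k axes."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    w_top = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w_top)


@dataclass
class NMDSResult:
    configuration: np.ndarray  # n_sites x k, centred at the origin
    stress: float  # Kruskal stress-1
    n_iterations: int
    converged: bool
    seed: int | None
    labels: list[str]

    def write_coords(self, path: str | Path) -> None:
        k = self.configuration.shape[1]
        df = pd.DataFrame(
            self.configuration,
            index=self.labels,
            columns=[f"axis{i + 1}" for i in range(k)],
        )
        df.index.name = "site_id"
        with open(path, "w") as fh:
            fh.write(f"# stress-1 = {self.stress:.6g}\n")
            df.to_csv(fh, float_format="%.10g")


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> NMDSResult:
    """Best-of-``n_starts`` NMDS configuration for a dissimilarity matrix.

    Start 1 is classical scaling of the input; starts 2..n_starts draw
    random Gaussian configurations from a seeded stream, so increasing
    ``n_starts`` with the same seed only extends the stream and can never
    worsen the reported best stress.
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    n = d.n
    if n < k + 2:
        raise DomainError(f"need at least k+2 = {k + 2} sites for k = {k}")
    if k >= n - 1:
        raise DomainError(f"k = {k} too large for n = {n} sites (need k < n-1)")
    off = d.condensed()
    if np.ptp(off) == 0:
        raise DegenerateMatrixError("all dissimilarities equal: NMDS undefined")
    if n_starts < 1:
        raise DomainError("n_starts must be >= 1")

    rng = np.random.default_rng(seed)
    inits = [classical_scaling(d.d, k)]
    for _ in range(n_starts - 1):
        inits.append(rng.normal(size=(n, k)))

    best = None
    for init in inits:
        X, stress, n_iter = smacof(
            d.d,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            return_n_iter=True,
        )
        if best is None or stress < best[1]:
            best = (X, float(stress), int(n_iter))

    X, stress, n_iter = best
    X = X - X.mean(axis=0, keepdims=True)
    return NMDSResult(
        configuration=X,
        stress=stress,
        n_iterations=n_iter,
        converged=n_iter < max_iter,
        seed=seed,
        labels=list(d.labels),
    )
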