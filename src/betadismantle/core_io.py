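"""Domain types, validation and CSV I/O for community and distance data.

The package analyses site-by-species tables (presence/absence or
abundance), per-site attributes (coordinates, climate, forest area,
import value) and labelled pairwise distance matrices.  Everything
downstream — beta-diversity partition, Mantel correlograms, matrix
regression — consumes the three containers defined here.

CSV conventions are deliberately rigid: comma-separated UTF-8, first
column holds the site id, header row holds species / attribute /
site labels.  Site-label matching between tables is exact-string and
case-sensitive; a mismatch raises instead of silently intersecting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetadismantleError",
    "LabelError",
    "ValueValidationError",
    "ModeError",
    "InsufficientDataError",
    "UndefinedPairError",
    "DegenerateMatrixError",
    "CollinearityError",
    "DomainError",
    "CommunityMatrix",
    "SiteAttributes",
    "DistanceMatrix",
    "read_community_table",
    "write_community_table",
    "read_site_attributes",
    "write_site_attributes",
    "read_distance_matrix",
    "write_distance_matrix",
    "drop_empty_sites",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class BetadismantleError(Exception):
    """Base class for all package errors."""


class LabelError(BetadismantleError):
    """Duplicate, missing or mismatched site/species labels."""


class ValueValidationError(BetadismantleError):
    """A value violates a container contract (negative abundance, NaN...)."""


class ModeError(BetadismantleError):
    """Non-binary values supplied where incidence (0/1) data is required."""


class InsufficientDataError(BetadismantleError):
    """Fewer than two usable sites remain; no pairwise analysis possible."""


class UndefinedPairError(BetadismantleError):
    """A pairwise index is undefined (e.g. both communities empty)."""


class DegenerateMatrixError(BetadismantleError):
    """A distance matrix is constant off-diagonal where variation is required."""


class CollinearityError(BetadismantleError):
    """A regression design matrix is rank-deficient."""


class DomainError(BetadismantleError):
    """A scalar argument lies outside its mathematical domain."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for x in labels:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise LabelError(f"duplicate {what} labels: {sorted(set(dups))}")
    return labels


@dataclass
class CommunityMatrix:
    """Site-by-species table.

    ``mode="incidence"`` holds strict 0/1 presence/absence values;
    ``mode="abundance"`` holds nonnegative quantities (e.g. the area
    covered by each forest type in each state).  ``guild_tag`` is a
    free-form label such as ``"bark/non-native"``.
    """

    site_ids: list[str]
    species_ids: list[str]
    values: np.ndarray
    mode: str = "incidence"
    guild_tag: str = ""

    def __post_init__(self) -> None:
        self.site_ids = _check_unique(self.site_ids, "site")
        self.species_ids = _check_unique(self.species_ids, "species")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValueValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueValidationError("community values must be finite")
        if np.any(self.values < 0):
            raise ValueValidationError("community values must be nonnegative")
        if self.mode not in ("incidence", "abundance"):
            raise ModeError(f"unknown mode {self.mode!r}")
        if self.mode == "incidence":
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                bad = self.values[~np.isin(self.values, (0.0, 1.0))]
                raise ModeError(
                    f"incidence mode requires 0/1 values; found e.g. {bad.flat[0]}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.species_ids)


@dataclass
class SiteAttributes:
    """Per-site covariates: centroid coordinates, climate, forest and trade.

    ``forest_area`` and ``import_value`` must be strictly positive because
    both are log-transformed when building predictor distance matrices.
    """

    table: pd.DataFrame

    REQUIRED = ("lon", "lat", "temp", "rain", "forest_area", "import_value")

    def __post_init__(self) -> None:
        df = self.table
        if "site_id" in df.columns:
            df = df.set_index("site_id")
        df.index = df.index.map(str)
        _check_unique(list(df.index), "site")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueValidationError(f"missing attribute columns: {missing}")
        df = df.copy()
        for c in self.REQUIRED:
            df[c] = pd.to_numeric(df[c])
        if not np.all(np.isfinite(df[list(self.REQUIRED)].to_numpy())):
            raise ValueValidationError("site attributes must be finite")
        if np.any(np.abs(df["lat"]) > 90):
            raise DomainError("latitude outside [-90, 90]")
        if np.any(np.abs(df["lon"]) > 180):
            raise DomainError("longitude outside [-180, 180]")
        if np.any(df["forest_area"] <= 0):
            raise ValueValidationError("forest_area must be strictly positive")
        if np.any(df["import_value"] <= 0):
            raise ValueValidationError("import_value must be strictly positive")
        self.table = df

    @property
    def site_ids(self) -> list[str]:
        return list(self.table.index)

    def reorder(self, site_ids: Sequence[str], allow_extra: bool = False) -> "SiteAttributes":
        """Return a copy ordered as ``site_ids``; exact-string match or
        LabelError.  ``allow_extra`` tolerates attribute rows for sites not
        requested (e.g. sites explicitly dropped from a community)."""
        want = [str(s) for s in site_ids]
        have = set(self.table.index)
        missing = [s for s in want if s not in have]
        extra = [] if allow_extra else sorted(have - set(want))
        if missing or extra:
            raise LabelError(
                f"site label mismatch: missing from attributes {missing}, "
                f"absent from community {extra}"
            )
        return SiteAttributes(self.table.loc[want].copy())

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix with zero diagonal — the currency of the
    whole pipeline.

    Metric producers (beta components, Bray-Curtis, haversine...) yield
    nonnegative entries; standardized regressors relax that via
    ``allow_negative`` since a centred matrix is a predictor, not a metric.
    """

    labels: list[str]
    d: np.ndarray
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.labels = _check_unique(self.labels, "site")
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueValidationError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.d)):
            raise ValueValidationError("distance matrix must be finite")
        if not np.allclose(self.d, self.d.T, rtol=0, atol=1e-12):
            raise ValueValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueValidationError("distance matrix diagonal must be exactly 0")
        if not self.allow_negative and np.any(self.d < 0):
            raise ValueValidationError("distance matrix entries must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Unfolded upper triangle (row-major, k = i<j order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def same_labels(self, other: "DistanceMatrix") -> bool:
        return self.labels == other.labels

    def require_same_labels(self, other: "DistanceMatrix") -> None:
        if not self.same_labels(other):
            raise LabelError("distance matrices have different site labels/order")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_community_table(
    path: str | Path, mode: str = "incidence", guild_tag: str = ""
) -> CommunityMatrix:
    """Read a site-by-species CSV (first column = site id, header = species)."""
    df = pd.read_csv(path, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueValidationError(f"non-numeric community values in {path}: {exc}")
    return CommunityMatrix(
        site_ids=list(df.index.map(str)),
        species_ids=list(df.columns.map(str)),
        values=values,
        mode=mode,
        guild_tag=guild_tag,
    )


def write_community_table(cm: CommunityMatrix, path: str | Path) -> None:
    fmt = "%d" if cm.mode == "incidence" else "%.10g"
    df = cm.to_frame()
    df.index.name = "site_id"
    df.to_csv(path, float_format=fmt)


def read_site_attributes(path: str | Path) -> SiteAttributes:
    return SiteAttributes(pd.read_csv(path))


def write_site_attributes(attrs: SiteAttributes, path: str | Path) -> None:
    out = attrs.table.copy()
    out.index.name = "site_id"
    out.to_csv(path)


def read_distance_matrix(path: str | Path, allow_negative: bool = False) -> DistanceMatrix:
    """Read a square CSV whose row labels equal its column labels."""
    df = pd.read_csv(path, index_col=0)
    rows = list(df.index.map(str))
    cols = list(df.columns.map(str))
    if rows != cols:
        raise LabelError("square distance CSV must have identical row/column labels")
    return DistanceMatrix(rows, df.to_numpy(dtype=float), allow_negative=allow_negative)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels)
    df.index.name = "site_id"
    df.to_csv(path, float_format="%.12g")


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def drop_empty_sites(cm: CommunityMatrix) -> tuple[CommunityMatrix, list[str]]:
    """Remove sites whose row sum is zero (no species recorded).

    States with no record of a guild carry no compositional information and
    make the Jaccard family undefined against other empty sites; dropping is
    explicit, never implicit.  Returns the reduced matrix and the dropped ids.
    """
    row_sums = cm.values.sum(axis=1)
    keep = row_sums > 0
    dropped = [s for s, k in zip(cm.site_ids, keep) if not k]
    if not dropped:
        return cm, []
    if int(keep.sum()) < 2:
        raise InsufficientDataError(
            f"fewer than 2 non-empty sites remain after dropping {dropped}"
        )
    out = CommunityMatrix(
        site_ids=[s for s, k in zip(cm.site_ids, keep) if k],
        species_ids=list(cm.species_ids),
        values=cm.values[keep],
        mode=cm.mode,
        guild_tag=cm.guild_tag,
    )
    return out, dropped
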