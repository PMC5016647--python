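"""Core data structures for site-by-species atlas analyses.

Canonical orientation everywhere: sites are rows, species are columns.
All matrices produced downstream (suitability, membership) share the site
and species ordering of the occurrence matrix they were computed from.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


def _check_unique(labels, what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class SiteGrid:
    """Cell centers of a study grid, projected coordinates in km.

    Site identifiers are unique; coordinates are arbitrary distinct points
    (regular lattices are a special case produced by the synthetic
    generator).
    """

    site_ids: tuple
    x: np.ndarray
    y: np.ndarray
    cell_size: float

    def __post_init__(self):
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if len(self.site_ids) != self.x.shape[0] or len(self.site_ids) != self.y.shape[0]:
            raise ValidationError("site_ids, x and y must have equal length")
        _check_unique(self.site_ids, "site")
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be positive")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def coords(self) -> np.ndarray:
        """(n_sites, 2) array of cell-center coordinates in km."""
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site_id": list(self.site_ids), "x": self.x, "y": self.y})


@dataclass
class OccurrenceMatrix:
    """Binary site x species incidence matrix.

    ``values[i, k]`` is 1 when species ``k`` was recorded in site ``i``.
    """

    sites: tuple
    species: tuple
    values: np.ndarray

    def __post_init__(self):
        self.sites = tuple(self.sites)
        self.species = tuple(self.species)
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.sites), len(self.species)):
            raise ValidationError(
                f"incidence shape {self.values.shape} does not match "
                f"{len(self.sites)} sites x {len(self.species)} species"
            )
        _check_unique(self.sites, "site")
        _check_unique(self.species, "species")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, k = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary incidence value {self.values[i, k]!r} at "
                f"site {self.sites[i]!r}, species {self.species[k]!r}"
            )
        self.values = self.values.astype(np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_occurrences(self) -> np.ndarray:
        """Number of occupied sites per species (column sums, N_k)."""
        return self.values.sum(axis=0)

    def site_richness(self) -> np.ndarray:
        """Observed richness per site (row sums, S_i)."""
        return self.values.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sites), columns=list(self.species))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OccurrenceMatrix":
        return cls(tuple(frame.index), tuple(frame.columns), frame.to_numpy())

    def check_aligned(self, grid: SiteGrid) -> None:
        if tuple(grid.site_ids) != self.sites:
            raise ValidationError("occurrence sites do not match grid sites")


@dataclass
class EnvTable:
    """Per-site environmental variables; one row per site, no missing values.

    At most one column may be categorical (a land-cover-like class); all
    others must be numeric.
    """

    data: pd.DataFrame  # indexed by site_id

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate site labels in environment table")
        if self.data.isna().any().any():
            col = self.data.columns[self.data.isna().any()][0]
            raise ValidationError(f"missing values in environment column {col!r}")
        n_cat = len(self.categorical_columns)
        if n_cat > 1:
            raise ValidationError("at most one categorical environment column is supported")

    @property
    def sites(self) -> tuple:
        return tuple(self.data.index)

    @property
    def continuous_columns(self) -> list:
        return [c for c in self.data.columns if pd.api.types.is_numeric_dtype(self.data[c])]

    @property
    def categorical_columns(self) -> list:
        return [c for c in self.data.columns if not pd.api.types.is_numeric_dtype(self.data[c])]

    def check_aligned(self, occ: OccurrenceMatrix) -> None:
        if self.sites != occ.sites:
            raise ValidationError("environment sites do not match occurrence sites")


@dataclass
class SuitabilityMatrix:
    """Per-site, per-species occurrence probabilities from one estimator.

    NaN marks species for which the estimator produced no prediction
    (e.g. an SDM that failed both the additive model and its fallback).
    """

    sites: tuple
    species: tuple
    values: np.ndarray
    method_tag: str

    def __post_init__(self):
        self.sites = tuple(self.sites)
        self.species = tuple(self.species)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sites), len(self.species)):
            raise ValidationError("suitability shape does not match labels")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("suitability values must lie in [0, 1]")


@dataclass
class MembershipMatrix:
    """Boolean site x species dark-diversity membership for one method."""

    sites: tuple
    species: tuple
    values: np.ndarray
    method_tag: str

    def __post_init__(self):
        self.sites = tuple(self.sites)
        self.species = tuple(self.species)
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.sites), len(self.species)):
            raise ValidationError("membership shape does not match labels")

    def dark_sizes(self) -> np.ndarray:
        """Dark-diversity size per site (row sums)."""
        return self.values.sum(axis=1)

    def check_disjoint(self, occ: OccurrenceMatrix) -> None:
        """Dark species are absent by definition: member => incidence 0."""
        if self.sites != occ.sites or self.species != occ.species:
            raise ValidationError("membership labels do not match occurrence labels")
        clash = self.values & (occ.values == 1)
        if clash.any():
            i, k = np.argwhere(clash)[0]
            raise ValidationError(
                f"membership overlaps occupancy at site {self.sites[i]!r}, "
                f"species {self.species[k]!r}"
            )


def filter_min_occurrence(occ: OccurrenceMatrix, min_occ: int) -> OccurrenceMatrix:
    """Drop species occupying fewer than ``min_occ`` sites (inclusive keep).

    Sites are retained even if their richness drops to zero. Raises
    :class:`ValidationError` when no species survives.
    """
    if min_occ < 1:
        raise ValidationError("min_occ must be >= 1")
    counts = occ.species_occurrences()
    keep = counts >= min_occ
    removed = [sp for sp, k in zip(occ.species, keep) if not k]
    for sp in removed:
        logger.info("min-occurrence filter removed species %s", sp)
    if not keep.any():
        raise ValidationError(
            f"min-occurrence filter (min_occ={min_occ}) removed every species"
        )
    if removed:
        logger.info(
            "min-occurrence filter: kept %d of %d species", int(keep.sum()), occ.n_species
        )
    species = tuple(sp for sp, k in zip(occ.species, keep) if k)
    return OccurrenceMatrix(occ.sites, species, occ.values[:, keep])
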