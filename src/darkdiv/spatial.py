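"""Dispersal and biogeographic eligibility filters.

Both filters only remove candidates from a membership matrix, never add:
a dark candidate must have a source population within a geographic radius,
and must occur somewhere in the focal cell's dispersion field (the cells
sharing more than a set fraction of its species).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .config import PipelineConfig
from .datamodel import MembershipMatrix, OccurrenceMatrix, SiteGrid, ValidationError

logger = logging.getLogger(__name__)


def radius_eligibility(occ: OccurrenceMatrix, grid: SiteGrid, radius_km: float) -> np.ndarray:
    """Boolean site x species matrix: species occurs within ``radius_km``
    (center-to-center, inclusive) of the focal cell."""
    if radius_km < 0:
        raise ValidationError("radius must be >= 0")
    occ.check_aligned(grid)
    d = squareform(pdist(grid.coords))
    near = d <= radius_km + 1e-9  # inclusive boundary; focal cell always counts
    return (near @ occ.values) > 0


def _dispersion_regions(occ: OccurrenceMatrix, fraction: float) -> np.ndarray:
    """Boolean site x site matrix: column s is in row i's dispersion field."""
    I = occ.values.astype(float)
    shared = I @ I.T  # shared[i, s] = |composition(i) & composition(s)|
    richness = I.sum(axis=1)
    region = shared > fraction * richness[:, None]  # strict: > fraction of focal's species
    region[np.arange(len(region)), np.arange(len(region))] = True  # focal always included
    empty = np.where(richness == 0)[0]
    if empty.size:
        # vacuous criterion at zero richness: field collapses to the focal cell
        region[empty] = False
        region[empty, empty] = True
        logger.info("dispersion field: %d empty focal sites restricted to themselves",
                    empty.size)
    return region


def dispersion_field(occ: OccurrenceMatrix, focal_site, fraction: float) -> set:
    """Site ids sharing strictly more than ``fraction`` of the focal cell's
    species, plus the focal cell itself."""
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie in (0, 1)")
    try:
        i = occ.sites.index(focal_site)
    except ValueError:
        raise ValidationError(f"unknown focal site {focal_site!r}") from None
    region = _dispersion_regions(occ, fraction)[i]
    return {occ.sites[s] for s in np.where(region)[0]}


def dispersion_eligibility(occ: OccurrenceMatrix, fraction: float) -> np.ndarray:
    """Boolean site x species matrix: species occurs in >=1 cell of the focal
    cell's dispersion field."""
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie in (0, 1)")
    region = _dispersion_regions(occ, fraction)
    return (region @ occ.values) > 0


def apply_filters(membership: MembershipMatrix, occ: OccurrenceMatrix, grid: SiteGrid,
                  config: PipelineConfig, with_log: bool = False):
    """Conjoin the environmental membership with both spatial filters.

    Pure conjunction, so order is irrelevant; logged as radius then
    dispersion field for readability. With ``with_log`` also returns a
    per-site frame of removal counts.
    """
    if membership.sites != occ.sites or membership.species != occ.species:
        raise ValidationError("membership labels do not match occurrence labels")
    rad = radius_eligibility(occ, grid, config.radius_km)
    disp = dispersion_eligibility(occ, config.dispersion_fraction)
    filtered = membership.values & rad & disp
    out = MembershipMatrix(membership.sites, membership.species, filtered,
                           membership.method_tag)
    if not with_log:
        return out
    log = pd.DataFrame({
        "site_id": list(membership.sites),
        "n_input": membership.values.sum(axis=1),
        "removed_radius": (membership.values & ~rad).sum(axis=1),
        "removed_dispersion": (membership.values & rad & ~disp).sum(axis=1),
        "n_output": filtered.sum(axis=1),
    })
    return out, log
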