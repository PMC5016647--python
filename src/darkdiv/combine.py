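"""Consensus/composite combination and per-site summaries.

Consensus dark diversity = species flagged by both methods (intersection);
composite = species flagged by at least one (union). Completeness of site
diversity = ln(observed richness / dark size), undefined when either count
is zero.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import MembershipMatrix, OccurrenceMatrix, ValidationError

logger = logging.getLogger(__name__)


def _check_labels(a: MembershipMatrix, b: MembershipMatrix) -> None:
    if a.sites != b.sites or a.species != b.species:
        raise ValidationError("membership matrices have mismatched site/species labels")


def consensus(mem_a: MembershipMatrix, mem_b: MembershipMatrix) -> MembershipMatrix:
    """Cellwise AND of two memberships."""
    _check_labels(mem_a, mem_b)
    return MembershipMatrix(mem_a.sites, mem_a.species,
                            mem_a.values & mem_b.values, "consensus")


def composite(mem_a: MembershipMatrix, mem_b: MembershipMatrix) -> MembershipMatrix:
    """Cellwise OR of two memberships."""
    _check_labels(mem_a, mem_b)
    return MembershipMatrix(mem_a.sites, mem_a.species,
                            mem_a.values | mem_b.values, "composite")


def completeness(observed: np.ndarray, dark: np.ndarray) -> np.ndarray:
    """ln(observed / dark); NaN where either count is zero."""
    observed = np.asarray(observed, dtype=float)
    dark = np.asarray(dark, dtype=float)
    ok = (observed > 0) & (dark > 0)
    out = np.full(observed.shape, np.nan)
    out[ok] = np.log(observed[ok] / dark[ok])
    return out


def summarize(occ: OccurrenceMatrix, memberships: dict) -> pd.DataFrame:
    """Per-site observed richness, dark size and completeness per method.

    ``memberships`` maps a method tag (``sco``, ``sdm``, ``consensus``,
    ``composite``) to its membership matrix. Sites where a method's dark
    size is zero get a missing completeness; their count is logged.
    """
    richness = occ.site_richness()
    frame = pd.DataFrame({"site_id": list(occ.sites), "observed_richness": richness})
    for tag, mem in memberships.items():
        if mem.sites != occ.sites:
            raise ValidationError(f"membership {tag!r} sites do not match occurrence sites")
        dark = mem.dark_sizes()
        frame[f"dark_{tag}"] = dark
        comp = completeness(richness, dark)
        n_missing = int(np.isnan(comp).sum())
        if n_missing:
            logger.info("completeness undefined for %d sites under method %s",
                        n_missing, tag)
        frame[f"completeness_{tag}"] = comp
    return frame
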