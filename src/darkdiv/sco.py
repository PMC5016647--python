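"""Species co-occurrence (SCO) estimator.

Suitability of an absent species at a site is scored by the Beals index:
the mean, over the species present at the site, of the conditional
frequency with which the focal species co-occurs with each of them:

    P_ij = (1 / S_i) * sum_k N_jk * I_ik / N_k        (k != j)

where S_i excludes the focal species j, N_k is the number of occurrences
of species k and N_jk the number of joint occurrences of j and k. A
species enters dark diversity at sites where it is absent and P exceeds a
per-species quantile of its values at occupied sites.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import MembershipMatrix, OccurrenceMatrix, SuitabilityMatrix, ValidationError

logger = logging.getLogger(__name__)


def beals_probabilities(occ: OccurrenceMatrix, leave_one_out: bool = False) -> SuitabilityMatrix:
    """Beals co-occurrence probabilities for every (site, species) pair.

    Counts include the focal site by default (the literal formula); with
    ``leave_one_out`` the focal site is removed from N_k and N_jk before
    scoring it. Sites where the focal species has no co-occurring neighbours
    (S_i = 0) get P = 0 and are logged — an empty neighbourhood carries no
    co-occurrence information.
    """
    I = occ.values.astype(float)
    N = I.sum(axis=0)
    if (N < 1).any():
        bad = occ.species[int(np.argmin(N))]
        raise ValidationError(f"species {bad!r} has no occurrences; filter first")
    C = I.T @ I  # joint-occurrence counts N_jk
    np.fill_diagonal(C, 0.0)
    S = I.sum(axis=1)
    s_excl = S[:, None] - I  # richness excluding the focal species
    if leave_one_out:
        numer = np.empty_like(I)
        for i in range(I.shape[0]):
            row = I[i]
            nk = N - row  # occurrences elsewhere
            w = np.divide(row, nk, out=np.zeros_like(row), where=nk > 0)
            base = C @ w  # sum_k row_k * N_jk / nk_k, k != j via zero diagonal
            # where j itself is present, its joint counts with each present k
            # each drop by one
            numer[i] = base - row * (w.sum() - w)
        P = np.divide(numer, s_excl, out=np.zeros_like(numer), where=s_excl > 0)
    else:
        W = I / N  # I_ik / N_k
        numer = W @ C.T
        P = np.divide(numer, s_excl, out=np.zeros_like(numer), where=s_excl > 0)
    n_flagged = int((s_excl == 0).sum())
    if n_flagged:
        logger.info("Beals: %d (site, species) pairs with empty neighbourhood set to 0",
                    n_flagged)
    return SuitabilityMatrix(occ.sites, occ.species, np.clip(P, 0.0, 1.0), "sco")


def species_thresholds(P: SuitabilityMatrix, occ: OccurrenceMatrix, q: float) -> pd.Series:
    """Per-species inclusion threshold: the empirical ``q``-quantile (linear
    interpolation between order statistics) of P at the species' occupied sites."""
    if not 0 <= q < 1:
        raise ValidationError("quantile must lie in [0, 1)")
    if P.species != occ.species or P.sites != occ.sites:
        raise ValidationError("suitability and occurrence labels do not match")
    out = np.empty(occ.n_species)
    for j in range(occ.n_species):
        present = occ.values[:, j] == 1
        if not present.any():
            raise ValidationError(
                f"species {occ.species[j]!r} occupies no site; cannot set threshold"
            )
        out[j] = np.quantile(P.values[present, j], q, method="linear")
    return pd.Series(out, index=list(occ.species), name="threshold")


def sco_membership(P: SuitabilityMatrix, occ: OccurrenceMatrix,
                   thresholds: pd.Series) -> MembershipMatrix:
    """Dark membership: absent and P strictly above the species threshold."""
    if list(thresholds.index) != list(occ.species):
        raise ValidationError("threshold index does not match species order")
    t = thresholds.to_numpy(float)
    member = (occ.values == 0) & (P.values > t[None, :])
    return MembershipMatrix(occ.sites, occ.species, member, "sco")


def estimate_sco(occ: OccurrenceMatrix, q: float = 0.05,
                 leave_one_out: bool = False):
    """Convenience wrapper: probabilities, thresholds and membership in one call."""
    P = beals_probabilities(occ, leave_one_out=leave_one_out)
    thresholds = species_thresholds(P, occ, q)
    membership = sco_membership(P, occ, thresholds)
    return P, thresholds, membership
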