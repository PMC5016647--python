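"""Species distribution modelling (SDM) estimator.

Per species: an additive logistic model (penalized B-spline terms per
continuous environmental variable, dummy-coded levels for an optional
categorical one), repeated random calibration/evaluation splits, a
TSS-optimal binarization threshold per split aggregated by mean, and a
final refit on all sites. A species is dark at a site when it is absent
and its final predicted probability is at or above its threshold.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import SplineTransformer, StandardScaler

from .config import PipelineConfig
from .datamodel import EnvTable, MembershipMatrix, OccurrenceMatrix, SuitabilityMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ThresholdFit:
    """TSS-optimal binarization of predicted probabilities for one species."""

    species_id: str
    threshold: float
    tss: float
    sensitivity: float
    specificity: float
    n_eval: int
    fallback_used: bool = False

    def __post_init__(self):
        assert abs(self.tss - (self.sensitivity + self.specificity - 1.0)) < 1e-9


def split_sites(n_sites: int, calibration_fraction: float, repeats: int, seed: int):
    """Random calibration/evaluation partitions; deterministic given seed."""
    if not 0 < calibration_fraction < 1:
        raise ValidationError("calibration_fraction must lie in (0, 1)")
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    n_cal = int(round(calibration_fraction * n_sites))
    if n_cal < 1 or n_cal >= n_sites:
        raise ValidationError(
            f"split of {n_sites} sites at fraction {calibration_fraction} leaves an "
            "empty calibration or evaluation set"
        )
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        perm = rng.permutation(n_sites)
        out.append((np.sort(perm[:n_cal]), np.sort(perm[n_cal:])))
    return out


def tss_best_threshold(pred, obs, grid_size: int = 0, species_id: str = "") -> ThresholdFit:
    """Threshold maximizing TSS = sensitivity + specificity - 1.

    A site is predicted present when ``pred >= threshold``. Candidates are
    the sorted unique predictions plus {0, 1}, or an even grid of
    ``grid_size`` points when requested. Ties break toward the smallest
    threshold.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs).astype(bool)
    if pred.shape != obs.shape:
        raise ValidationError("pred and obs must have the same length")
    n_pos = int(obs.sum())
    n_neg = obs.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("observations must contain both classes")
    if grid_size > 0:
        cand = np.linspace(0.0, 1.0, grid_size)
    else:
        cand = np.unique(np.concatenate([pred, [0.0, 1.0]]))
    hit = pred[:, None] >= cand[None, :]
    tp = (hit & obs[:, None]).sum(axis=0)
    fp = (hit & ~obs[:, None]).sum(axis=0)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # first max = smallest candidate, cand sorted ascending
    return ThresholdFit(species_id, float(cand[best]), float(tss[best]),
                        float(sens[best]), float(spec[best]), int(obs.size))


class _DesignBuilder:
    """Shared basis expansion: B-splines per continuous variable, dummies for
    the categorical one. Built once on the full site table so every model,
    regardless of its calibration subset, predicts on the same basis."""

    def __init__(self, env: EnvTable, n_knots: int = 4, degree: int = 3):
        cont = env.data[env.continuous_columns].to_numpy(float)
        self._spline = None
        parts = []
        if cont.shape[1]:
            # constant columns break knot placement; keep them as raw terms
            variable = cont.std(axis=0) > 0
            if variable.any():
                self._spline = SplineTransformer(
                    n_knots=n_knots, degree=degree, include_bias=False
                )
                parts.append(self._spline.fit_transform(cont[:, variable]))
            if (~variable).any():
                parts.append(cont[:, ~variable])
            self._variable = variable
        self._cont_raw = cont
        for col in env.categorical_columns:
            dummies = pd.get_dummies(env.data[col], drop_first=True)
            parts.append(dummies.to_numpy(float))
        self.design = np.hstack(parts) if parts else np.zeros((len(env.sites), 0))
        self.quad = self._quadratic(cont)

    @staticmethod
    def _quadratic(cont: np.ndarray) -> np.ndarray:
        scaler = StandardScaler()
        sd = cont.std(axis=0)
        keep = cont[:, sd > 0]
        if keep.shape[1] == 0:
            return np.zeros((cont.shape[0], 0))
        z = scaler.fit_transform(keep)
        return np.hstack([z, z ** 2])


@dataclass
class SpeciesModel:
    """Fitted per-species occurrence model over the full site table."""

    species_id: str
    _clf: object
    _design: np.ndarray
    fallback_used: bool = False

    def predict(self, rows=None) -> np.ndarray:
        """Predicted occurrence probability for the given site rows (all by default)."""
        X = self._design if rows is None else self._design[rows]
        if self._clf is None:  # intercept-only degenerate fit
            return np.full(X.shape[0], self._prevalence)
        return self._clf.predict_proba(X)[:, 1]


def fit_species_model(builder: _DesignBuilder, occ_j, rows=None, ridge: float = 1.0,
                      species_id: str = "") -> SpeciesModel:
    """Fit the additive logistic model on a row subset; fall back to a
    linear+quadratic logistic regression when the smooth fit fails."""
    y = np.asarray(occ_j).astype(int)
    rows = np.arange(y.size) if rows is None else np.asarray(rows)
    y_fit = y[rows]
    if len(np.unique(y_fit)) < 2:
        raise ValidationError("calibration data must contain both classes")

    def _try(design: np.ndarray):
        clf = LogisticRegression(C=ridge, solver="lbfgs", max_iter=1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(design[rows], y_fit)
        if not np.isfinite(clf.coef_).all() or not np.isfinite(clf.intercept_).all():
            raise FloatingPointError("non-finite coefficients")
        return clf

    try:
        clf = _try(builder.design)
        return SpeciesModel(species_id, clf, builder.design)
    except Exception as exc:  # noqa: BLE001 - any fit failure triggers the fallback
        logger.warning("species %s: additive fit failed (%s); using quadratic fallback",
                       species_id, exc)
    clf = _try(builder.quad)  # raises to the caller if the fallback fails too
    return SpeciesModel(species_id, clf, builder.quad, fallback_used=True)


@dataclass
class SdmResult:
    membership: MembershipMatrix
    threshold_fits: list
    suitability: SuitabilityMatrix
    excluded_species: list = field(default_factory=list)


def sdm_membership(env: EnvTable, occ: OccurrenceMatrix, config: PipelineConfig) -> SdmResult:
    """Full SDM estimator for every species in the occurrence matrix.

    Species that are all-present, all-absent, yield no usable evaluation
    split, or fail both the additive model and its fallback are excluded
    (their membership column stays empty and their predictions NaN).
    """
    env.check_aligned(occ)
    builder = _DesignBuilder(env, n_knots=config.spline_knots, degree=config.spline_degree)
    splits = split_sites(occ.n_sites, config.sdm_split, config.sdm_repeats, config.seed)
    n_sites, n_species = occ.n_sites, occ.n_species
    member = np.zeros((n_sites, n_species), dtype=bool)
    probs = np.full((n_sites, n_species), np.nan)
    fits, excluded = [], []
    for j, sp in enumerate(occ.species):
        y = occ.values[:, j]
        if y.sum() == 0 or y.sum() == n_sites:
            excluded.append(sp)
            logger.info("SDM: species %s is single-class; excluded", sp)
            continue
        thresholds, n_eval, fallback = [], 0, False
        try:
            for cal, ev in splits:
                if len(np.unique(y[cal])) < 2 or len(np.unique(y[ev])) < 2:
                    continue
                model = fit_species_model(builder, y, rows=cal, ridge=config.sdm_ridge,
                                          species_id=sp)
                fallback = fallback or model.fallback_used
                fit = tss_best_threshold(model.predict(ev), y[ev],
                                         config.threshold_grid_size, sp)
                thresholds.append(fit.threshold)
                n_eval += fit.n_eval
            if not thresholds:
                excluded.append(sp)
                logger.info("SDM: species %s had no usable evaluation split; excluded", sp)
                continue
            final = fit_species_model(builder, y, ridge=config.sdm_ridge, species_id=sp)
        except ValidationError:
            excluded.append(sp)
            logger.info("SDM: species %s failed model and fallback; excluded", sp)
            continue
        fallback = fallback or final.fallback_used
        thr = float(np.mean(thresholds))
        p = final.predict()
        probs[:, j] = p
        member[:, j] = (y == 0) & (p >= thr)
        # summary skill at the aggregated threshold, on the full-data refit
        pos, neg = y == 1, y == 0
        sens = float((p[pos] >= thr).mean())
        spec = float((p[neg] < thr).mean())
        fits.append(ThresholdFit(sp, thr, sens + spec - 1.0, sens, spec, n_eval, fallback))
    membership = MembershipMatrix(occ.sites, occ.species, member, "sdm")
    suitability = SuitabilityMatrix(occ.sites, occ.species, probs, "sdm")
    return SdmResult(membership, fits, suitability, excluded)


def threshold_fits_frame(fits) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "species_id": f.species_id, "threshold": f.threshold, "tss": f.tss,
            "sensitivity": f.sensitivity, "specificity": f.specificity,
            "n_eval": f.n_eval, "fallback_used": int(f.fallback_used),
        }
        for f in fits
    ])
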