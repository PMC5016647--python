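"""Statistics comparing two dark-diversity estimates.

Per site: the overlap coefficient (|A & B| / min(|A|, |B|)) and an exact
upper-tail hypergeometric probability of seeing at least the observed
overlap when one method's picks are drawn at random from the candidate
universe. Across sites: summaries of those p-values and a type II
(major-axis) regression of the ln-transformed dark sizes against the 1:1
line.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MembershipMatrix, OccurrenceMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class OverlapTest:
    site_id: str
    N: int        # candidate universe size (absent, eligible species)
    x1: int       # dark size, method 1
    x2: int       # dark size, method 2
    overlap: int
    overlap_coefficient: float  # NaN when min(x1, x2) = 0
    p_value: float


@dataclass
class Type2Fit:
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    r2: float
    n: int
    includes_one: bool
    method: str = "ma"


def overlap_coefficient(set_a, set_b) -> float:
    """|A & B| / min(|A|, |B|); NaN when either set is empty."""
    set_a, set_b = set(set_a), set(set_b)
    smaller = min(len(set_a), len(set_b))
    if smaller == 0:
        return float("nan")
    return len(set_a & set_b) / smaller


def hypergeom_overlap_p(N: int, x1: int, x2: int, overlap: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(N, x2, x1): draw x1 species
    without replacement from N of which x2 are marked."""
    if not 0 <= x1 <= N:
        raise ValidationError(f"need 0 <= x1 <= N, got x1={x1}, N={N}")
    if not 0 <= x2 <= N:
        raise ValidationError(f"need 0 <= x2 <= N, got x2={x2}, N={N}")
    lo, hi = max(0, x1 + x2 - N), min(x1, x2)
    if not lo <= overlap <= hi:
        raise ValidationError(
            f"need max(0, x1+x2-N) <= overlap <= min(x1, x2): "
            f"{lo} <= {overlap} <= {hi} violated"
        )
    return float(stats.hypergeom.sf(overlap - 1, N, x2, x1))


def overlap_summary(tests, alpha: float = 0.05):
    """(mean p, median p, fraction of sites with p > alpha) over defined p-values."""
    p = np.array([t.p_value for t in tests], dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValidationError("no sites with a defined overlap p-value")
    return float(p.mean()), float(np.median(p)), float((p > alpha).mean())


def _ma_slope(sxx: float, syy: float, sxy: float) -> float:
    return (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy ** 2)) / (2 * sxy)


def major_axis_fit(x, y, ci_level: float = 0.95, method: str = "ma") -> Type2Fit:
    """Type II regression of y on x with a symmetric error model.

    ``ma`` (default) fits the major axis of the scatter; its confidence
    interval rotates the axis by the classical F-based angle. ``sma`` fits
    the standardized major axis with its textbook CI. The intercept passes
    through the means; r2 is the squared Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError("type II regression needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("x and y must not be constant")
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    r2 = sxy ** 2 / (sxx * syy)
    f_crit = stats.f.ppf(ci_level, 1, n - 2)
    if method == "ma":
        if sxy == 0:
            raise ValidationError("zero covariance: major-axis slope undefined")
        slope = _ma_slope(sxx, syy, sxy)
        tr = sxx + syy
        det = sxx * syy - sxy ** 2
        disc = np.sqrt(tr ** 2 - 4 * det)
        lam1, lam2 = (tr + disc) / 2, (tr - disc) / 2
        if lam2 <= 0:  # perfectly collinear scatter: the axis is exact
            lo = hi = slope
        else:
            h = f_crit / ((lam1 / lam2 + lam2 / lam1 - 2) * (n - 2))
            if h >= 1:
                lo, hi = -np.inf, np.inf
            else:
                a = np.sqrt(h / (1 - h))  # tangent of the rotation half-angle
                theta = np.arctan(slope)
                lo = np.tan(theta - np.arctan(a))
                hi = np.tan(theta + np.arctan(a))
                if lo > hi:  # rotation crossed the vertical
                    lo, hi = -np.inf, np.inf
    elif method == "sma":
        if sxy == 0:
            raise ValidationError("zero covariance: SMA slope sign undefined")
        slope = np.sign(sxy) * np.sqrt(syy / sxx)
        b = f_crit * (1 - r2) / (n - 2)
        lo = slope * (np.sqrt(b + 1) - np.sqrt(b))
        hi = slope * (np.sqrt(b + 1) + np.sqrt(b))
        if slope < 0:
            lo, hi = hi, lo
    else:
        raise ValidationError(f"unknown type II method {method!r}")
    intercept = y.mean() - slope * x.mean()
    return Type2Fit(float(slope), float(intercept), float(lo), float(hi),
                    float(r2), int(n), bool(lo <= 1.0 <= hi), method)


@dataclass
class ComparisonReport:
    tests: list
    mean_p: float
    median_p: float
    fraction_p_gt_alpha: float
    alpha: float
    mean_overlap_coefficient: float
    overlap_q25: float
    overlap_q75: float
    type2: Type2Fit | None
    n_regression: int
    n_excluded_zero: int
    richness_correlations: dict

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.tests])

    def to_dict(self) -> dict:
        d = {
            "mean_p": self.mean_p,
            "median_p": self.median_p,
            "fraction_p_gt_alpha": self.fraction_p_gt_alpha,
            "alpha": self.alpha,
            "mean_overlap_coefficient": self.mean_overlap_coefficient,
            "overlap_q25": self.overlap_q25,
            "overlap_q75": self.overlap_q75,
            "type2": None if self.type2 is None else asdict(self.type2),
            "n_regression": self.n_regression,
            "n_excluded_zero": self.n_excluded_zero,
            "richness_correlations": self.richness_correlations,
        }
        return d

    def to_json(self, path, metadata=None) -> None:
        payload = self.to_dict()
        if metadata:
            payload["metadata"] = metadata
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
            fh.write("\n")


def compare_methods(mem_a: MembershipMatrix, mem_b: MembershipMatrix,
                    occ: OccurrenceMatrix, eligibility: np.ndarray | None = None,
                    alpha: float = 0.05, ci_level: float = 0.95,
                    type2_method: str = "ma") -> ComparisonReport:
    """Full per-site and across-site comparison of two membership matrices.

    ``eligibility`` (boolean site x species) restricts the hypergeometric
    candidate universe to species passing the spatial filters; when None the
    universe is every species absent from the site. Sites where either dark
    size is zero are excluded from the ln-size regression (count reported).
    """
    if mem_a.sites != mem_b.sites or mem_a.species != mem_b.species:
        raise ValidationError("membership matrices have mismatched labels")
    if mem_a.sites != occ.sites or mem_a.species != occ.species:
        raise ValidationError("membership labels do not match occurrence labels")
    absent = occ.values == 0
    universe = absent if eligibility is None else (absent & eligibility)
    a_in = mem_a.values & universe
    b_in = mem_b.values & universe
    if (mem_a.values & ~universe).any() or (mem_b.values & ~universe).any():
        logger.warning("some dark members fall outside the candidate universe; "
                       "they are ignored in the overlap tests")
    tests = []
    for i, site in enumerate(occ.sites):
        N = int(universe[i].sum())
        x1 = int(a_in[i].sum())
        x2 = int(b_in[i].sum())
        ov = int((a_in[i] & b_in[i]).sum())
        coef = float("nan") if min(x1, x2) == 0 else ov / min(x1, x2)
        p = hypergeom_overlap_p(N, x1, x2, ov) if N > 0 else float("nan")
        tests.append(OverlapTest(site, N, x1, x2, ov, coef, p))
    mean_p, median_p, frac = overlap_summary(tests, alpha)
    coefs = np.array([t.overlap_coefficient for t in tests])
    coefs = coefs[~np.isnan(coefs)]
    if coefs.size:
        mean_coef = float(coefs.mean())
        q25, q75 = (float(q) for q in np.quantile(coefs, [0.25, 0.75]))
    else:
        mean_coef = q25 = q75 = float("nan")
    sizes_a = mem_a.dark_sizes().astype(float)
    sizes_b = mem_b.dark_sizes().astype(float)
    usable = (sizes_a > 0) & (sizes_b > 0)
    n_excluded = int((~usable).sum())
    type2 = None
    if usable.sum() >= 3:
        try:
            type2 = major_axis_fit(np.log(sizes_a[usable]), np.log(sizes_b[usable]),
                                   ci_level, type2_method)
        except ValidationError as exc:
            logger.warning("type II regression skipped: %s", exc)
    else:
        logger.warning("type II regression skipped: only %d usable sites",
                       int(usable.sum()))
    richness = occ.site_richness().astype(float)
    correlations = {}
    for tag, sizes in ((mem_a.method_tag, sizes_a), (mem_b.method_tag, sizes_b)):
        if np.ptp(sizes) > 0 and np.ptp(richness) > 0:
            correlations[f"dark_{tag}_vs_richness"] = float(
                np.corrcoef(sizes, richness)[0, 1]
            )
    return ComparisonReport(
        tests=tests, mean_p=mean_p, median_p=median_p, fraction_p_gt_alpha=frac,
        alpha=alpha, mean_overlap_coefficient=mean_coef, overlap_q25=q25,
        overlap_q75=q75, type2=type2, n_regression=int(usable.sum()),
        n_excluded_zero=n_excluded, richness_correlations=correlations,
    )
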