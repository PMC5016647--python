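"""Synthetic atlas generator with known ground truth.

Builds a regular grid of cells, smooth environmental gradients with
spatially autocorrelated noise, virtual species with Gaussian (unimodal)
niche responses and optional dispersal-limited ranges, and Bernoulli-sampled
occurrence matrices. Because sampling is probabilistic and some species are
range-limited, suitable-but-absent cells exist by construction, giving every
dataset a known "true dark" reference set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .datamodel import EnvTable, OccurrenceMatrix, SiteGrid, ValidationError
from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NicheSpec:
    """One virtual species: Gaussian niche optima/breadths plus a dispersal range."""

    species_id: str
    optima: np.ndarray       # one per continuous environmental variable
    breadths: np.ndarray     # positive, same length as optima
    max_prob: float          # occurrence probability at the niche optimum
    range_center: np.ndarray  # (x, y) in km
    range_radius: float      # km; inf = cosmopolitan

    def __post_init__(self):
        object.__setattr__(self, "optima", np.asarray(self.optima, dtype=float))
        object.__setattr__(self, "breadths", np.asarray(self.breadths, dtype=float))
        object.__setattr__(self, "range_center", np.asarray(self.range_center, dtype=float))
        if (self.breadths <= 0).any():
            raise ValidationError("niche breadths must be positive")
        if not 0 < self.max_prob <= 1:
            raise ValidationError("max_prob must lie in (0, 1]")

    @property
    def is_range_limited(self) -> bool:
        return np.isfinite(self.range_radius)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a sampled occurrence matrix.

    ``dark_in_range`` counts a suitable absent cell as true dark only inside
    the species' dispersal range; ``dark_anywhere`` ignores the range. Both
    variants are kept because which one is "the" truth depends on whether a
    dispersal filter is being evaluated.
    """

    sites: tuple
    species: tuple
    suitability: np.ndarray      # realized occurrence probability ignoring range
    in_range: np.ndarray         # bool, site x species
    dark_in_range: np.ndarray    # bool
    dark_anywhere: np.ndarray    # bool
    truth_cutoff: float
    seed: int

    def dark(self, respect_range: bool) -> np.ndarray:
        return self.dark_in_range if respect_range else self.dark_anywhere

    def to_frame(self) -> pd.DataFrame:
        n_sites, n_species = len(self.sites), len(self.species)
        return pd.DataFrame({
            "site_id": np.repeat(list(self.sites), n_species),
            "species_id": np.tile(list(self.species), n_sites),
            "true_suitability": self.suitability.ravel(),
            "in_range": self.in_range.ravel().astype(int),
            "true_dark_in_range": self.dark_in_range.ravel().astype(int),
            "true_dark_anywhere": self.dark_anywhere.ravel().astype(int),
        })


def generate_grid(nx: int, ny: int, cell_size: float) -> SiteGrid:
    """Regular nx x ny lattice with cell centers at ((i+0.5)c, (j+0.5)c)."""
    if nx < 1 or ny < 1:
        raise ValidationError("grid dimensions must be >= 1")
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ix, iy = ix.ravel(), iy.ravel()
    site_ids = tuple(f"c{i:02d}_{j:02d}" for i, j in zip(ix, iy))
    return SiteGrid(site_ids, (ix + 0.5) * cell_size, (iy + 0.5) * cell_size, cell_size)


def _correlated_noise(coords: np.ndarray, scale: float, autocorr_range: float,
                      rng: np.random.Generator) -> np.ndarray:
    """One draw from a Gaussian field with exponential covariance exp(-d/range)."""
    n = coords.shape[0]
    z = rng.standard_normal(n)
    if scale == 0:
        return np.zeros(n)
    if autocorr_range <= 0:
        return scale * z
    d = squareform(pdist(coords))
    cov = np.exp(-d / autocorr_range)
    # jitter keeps the Cholesky factorization stable for near-singular fields
    cov[np.diag_indices_from(cov)] += 1e-10
    chol = np.linalg.cholesky(cov)
    return scale * (chol @ z)


def generate_environment(grid: SiteGrid, n_vars: int, gradient_amplitude: float,
                         noise_scale: float, autocorr_range: float, seed: int,
                         n_cover_classes: int = 0) -> EnvTable:
    """Smooth south-north gradients plus spatially autocorrelated noise.

    Each variable spans exactly ``gradient_amplitude`` units along the
    gradient (sign alternates between variables), with an additive noise
    field of marginal SD ``noise_scale``.
    """
    if n_vars < 1:
        raise ValidationError("n_vars must be >= 1")
    if gradient_amplitude < 0 or noise_scale < 0 or autocorr_range < 0:
        raise ValidationError("amplitudes, scales and ranges must be non-negative")
    rng = np.random.default_rng(seed)
    coords = grid.coords
    span = grid.y.max() - grid.y.min()
    ynorm = (grid.y - grid.y.min()) / span if span > 0 else np.zeros(grid.n_sites)
    columns = {}
    for v in range(n_vars):
        sign = 1.0 if v % 2 == 0 else -1.0
        noise = _correlated_noise(coords, noise_scale, autocorr_range, rng)
        columns[f"env{v + 1}"] = sign * gradient_amplitude * ynorm + noise
    if n_cover_classes > 0:
        field = _correlated_noise(coords, 1.0, autocorr_range, rng)
        edges = np.quantile(field, np.linspace(0, 1, n_cover_classes + 1)[1:-1])
        classes = np.digitize(field, edges)
        columns["cover"] = pd.Categorical([f"class{c}" for c in classes])
    frame = pd.DataFrame(columns, index=pd.Index(list(grid.site_ids), name="site_id"))
    return EnvTable(frame)


def generate_species_pool(n_species: int, env: EnvTable, grid: SiteGrid,
                          niche_breadth_range=(0.8, 1.6),
                          max_prob_range=(0.6, 1.0),
                          range_limited_fraction: float = 0.5,
                          range_radius_range=(200.0, 500.0),
                          seed: int = 0) -> list:
    """Draw virtual species with optima inside the observed environmental span.

    Breadths are drawn in units of each variable's SD. Exactly
    ``round(range_limited_fraction * n_species)`` species receive a finite
    dispersal range centred on a random cell.
    """
    if n_species < 1:
        raise ValidationError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    cont = env.data[env.continuous_columns].to_numpy(float)
    lo, hi = cont.min(axis=0), cont.max(axis=0)
    sd = cont.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    n_limited = int(round(range_limited_fraction * n_species))
    limited = np.zeros(n_species, dtype=bool)
    limited[rng.choice(n_species, size=n_limited, replace=False)] = True
    coords = grid.coords
    pool = []
    for s in range(n_species):
        optima = rng.uniform(lo, hi)
        breadths = rng.uniform(*niche_breadth_range, size=cont.shape[1]) * sd
        max_prob = rng.uniform(*max_prob_range)
        center = coords[rng.integers(coords.shape[0])]
        radius = rng.uniform(*range_radius_range) if limited[s] else np.inf
        pool.append(NicheSpec(f"sp{s + 1:03d}", optima, breadths, max_prob, center, radius))
    return pool


def true_suitability(env: EnvTable, niches) -> np.ndarray:
    """Gaussian niche response: max_prob * exp(-sum((env-opt)^2 / 2 breadth^2))."""
    cont = env.data[env.continuous_columns].to_numpy(float)
    out = np.empty((cont.shape[0], len(niches)))
    for j, sp in enumerate(niches):
        z = (cont - sp.optima) / sp.breadths
        out[:, j] = sp.max_prob * np.exp(-0.5 * (z ** 2).sum(axis=1))
    return out


def sample_occurrences(grid: SiteGrid, env: EnvTable, niches, truth_cutoff: float,
                       seed: int) -> tuple:
    """Bernoulli-sample occurrences from niche suitability inside each range.

    Returns ``(OccurrenceMatrix, SyntheticTruth)``. A cell is "true dark"
    for a species when the species is absent and its suitability reaches
    ``truth_cutoff * max_prob``; the range-restricted variant additionally
    requires the cell to lie inside the species' dispersal range.
    """
    rng = np.random.default_rng(seed)
    suit = true_suitability(env, niches)
    coords = grid.coords
    centers = np.array([sp.range_center for sp in niches])
    radii = np.array([sp.range_radius for sp in niches])
    dist = cdist(coords, centers)
    in_range = dist <= radii[None, :]
    p_occ = suit * in_range
    incidence = (rng.random(p_occ.shape) < p_occ).astype(np.int8)
    cutoffs = truth_cutoff * np.array([sp.max_prob for sp in niches])
    suitable = suit >= cutoffs[None, :]
    absent = incidence == 0
    truth = SyntheticTruth(
        sites=tuple(grid.site_ids),
        species=tuple(sp.species_id for sp in niches),
        suitability=suit,
        in_range=in_range,
        dark_in_range=absent & suitable & in_range,
        dark_anywhere=absent & suitable,
        truth_cutoff=truth_cutoff,
        seed=seed,
    )
    occ = OccurrenceMatrix(truth.sites, truth.species, incidence)
    return occ, truth


def generate_dataset(config: PipelineConfig):
    """Full synthetic scenario from one config: grid, environment, pool, sampling.

    Sub-seeds are derived deterministically from ``config.seed`` so the
    stages stay independent yet reproducible.
    """
    ss = np.random.SeedSequence(config.seed).spawn(3)
    env_seed, pool_seed, occ_seed = (int(s.generate_state(1)[0]) for s in ss)
    grid = generate_grid(config.nx, config.ny, config.cell_size_km)
    env = generate_environment(
        grid, config.n_env_vars, config.gradient_amplitude, config.noise_scale,
        config.autocorr_range_km, env_seed, config.n_cover_classes,
    )
    niches = generate_species_pool(
        config.n_species, env, grid,
        niche_breadth_range=config.niche_breadth_range,
        max_prob_range=config.max_prob_range,
        range_limited_fraction=config.range_limited_fraction,
        range_radius_range=config.range_radius_range_km,
        seed=pool_seed,
    )
    occ, truth = sample_occurrences(grid, env, niches, config.truth_cutoff, occ_seed)
    logger.info(
        "synthetic atlas: %d sites, %d species, %d occupied cells, %d true-dark cells",
        occ.n_sites, occ.n_species, int(occ.values.sum()), int(truth.dark_anywhere.sum()),
    )
    return grid, env, niches, occ, truth
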