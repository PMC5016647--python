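"""Pipeline configuration: every tunable constant in one place.

Defaults follow atlas-scale practice: species kept when occupying at least
20 cells, a 5% co-occurrence inclusion quantile, 80/20 calibration splits,
a 500-km dispersal radius and a >50% shared-composition dispersion field.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    # species filter
    min_occ: int = 20
    # co-occurrence (SCO) estimator
    sco_quantile: float = 0.05
    beals_leave_one_out: bool = False
    # SDM estimator
    sdm_split: float = 0.8
    sdm_repeats: int = 5
    threshold_grid_size: int = 0  # 0 -> candidate thresholds = observed predictions + {0,1}
    sdm_ridge: float = 1.0  # inverse-variance weight of the coefficient shrinkage
    spline_knots: int = 4
    spline_degree: int = 3
    # spatial filters
    radius_km: float = 500.0
    dispersion_fraction: float = 0.5
    # method comparison
    hypergeom_universe: str = "filtered"  # or "all_absent"
    type2_method: str = "ma"  # or "sma"
    ci_level: float = 0.95
    alpha: float = 0.05
    # synthetic atlas
    nx: int = 20
    ny: int = 20
    cell_size_km: float = 50.0
    n_env_vars: int = 4
    gradient_amplitude: float = 6.0
    noise_scale: float = 1.0
    autocorr_range_km: float = 300.0
    n_cover_classes: int = 0
    n_species: int = 80
    niche_breadth_range: tuple = (1.0, 1.8)  # in units of each variable's SD
    max_prob_range: tuple = (0.7, 1.0)
    range_limited_fraction: float = 0.5
    range_radius_range_km: tuple = (200.0, 500.0)
    truth_cutoff: float = 0.5  # fraction of each species' max_prob
    truth_respects_range: bool = False
    # reproducibility
    seed: int = 1

    def __post_init__(self):
        for name in ("sco_quantile", "sdm_split", "dispersion_fraction",
                     "ci_level", "alpha", "range_limited_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("sco_quantile", "sdm_split", "dispersion_fraction", "ci_level"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.radius_km < 0:
            raise ValueError("radius_km must be >= 0")
        if self.min_occ < 1:
            raise ValueError("min_occ must be >= 1")
        if self.sdm_repeats < 1:
            raise ValueError("sdm_repeats must be >= 1")
        if self.hypergeom_universe not in ("filtered", "all_absent"):
            raise ValueError("hypergeom_universe must be 'filtered' or 'all_absent'")
        if self.type2_method not in ("ma", "sma"):
            raise ValueError("type2_method must be 'ma' or 'sma'")

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = cls.__dataclass_fields__
        unknown = set(mapping) - set(known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        clean = {}
        for k, v in mapping.items():
            if isinstance(v, list):
                v = tuple(v)
            clean[k] = v
        return cls(**clean)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"configuration file {path} must contain a mapping")
        return cls.from_mapping(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
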