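"""End-to-end orchestration: simulate, estimate, filter, combine, compare.

Every output CSV/JSON carries the seed and the parameters that produced it
in ``# key=value`` metadata lines, and nothing time-dependent, so reruns of
the same config are bit-identical.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ddio
from .combine import composite, consensus, summarize
from .compare import ComparisonReport, compare_methods
from .config import PipelineConfig
from .datamodel import (
    EnvTable,
    MembershipMatrix,
    OccurrenceMatrix,
    SiteGrid,
    SuitabilityMatrix,
    filter_min_occurrence,
)
from .sco import estimate_sco
from .sdm import SdmResult, sdm_membership, threshold_fits_frame
from .spatial import apply_filters, dispersion_eligibility, radius_eligibility
from .synthetic import SyntheticTruth, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    grid: SiteGrid
    env: EnvTable
    occ_raw: OccurrenceMatrix
    occ: OccurrenceMatrix            # after the min-occurrence filter
    truth: SyntheticTruth | None
    sco_suitability: SuitabilityMatrix
    sco_thresholds: pd.Series
    sco_membership_raw: MembershipMatrix
    sco_membership: MembershipMatrix  # after spatial filters
    sdm: SdmResult
    sdm_membership: MembershipMatrix  # after spatial filters
    consensus: MembershipMatrix
    composite: MembershipMatrix
    summary: pd.DataFrame
    report: ComparisonReport
    filter_logs: dict


def _metadata(config: PipelineConfig) -> dict:
    meta = {"seed": config.seed}
    for key, val in sorted(config.to_dict().items()):
        if key != "seed":
            meta[key] = val
    return meta


def run_pipeline(config: PipelineConfig,
                 grid: SiteGrid | None = None,
                 env: EnvTable | None = None,
                 occ: OccurrenceMatrix | None = None) -> PipelineResult:
    """Run the whole analysis; inputs default to a synthetic atlas.

    Passing ``grid``/``env``/``occ`` together runs the same analysis on
    external data instead of simulating.
    """
    truth = None
    if occ is None:
        grid, env, _, occ, truth = generate_dataset(config)
    elif grid is None or env is None:
        raise ValueError("external occurrence data needs a grid and an environment table")
    occ_raw = occ
    occ = filter_min_occurrence(occ_raw, config.min_occ)
    env_aligned = EnvTable(env.data.loc[list(occ.sites)])

    sco_P, sco_thr, sco_mem_raw = estimate_sco(
        occ, q=config.sco_quantile, leave_one_out=config.beals_leave_one_out
    )
    sdm_res = sdm_membership(env_aligned, occ, config)

    sco_mem, sco_log = apply_filters(sco_mem_raw, occ, grid, config, with_log=True)
    sdm_mem, sdm_log = apply_filters(sdm_res.membership, occ, grid, config, with_log=True)

    cons = consensus(sco_mem, sdm_mem)
    comp = composite(sco_mem, sdm_mem)
    summary = summarize(occ, {
        "sco": sco_mem, "sdm": sdm_mem, "consensus": cons, "composite": comp,
    })

    eligibility = None
    if config.hypergeom_universe == "filtered":
        eligibility = (radius_eligibility(occ, grid, config.radius_km)
                       & dispersion_eligibility(occ, config.dispersion_fraction))
    report = compare_methods(
        sco_mem, sdm_mem, occ, eligibility=eligibility, alpha=config.alpha,
        ci_level=config.ci_level, type2_method=config.type2_method,
    )
    return PipelineResult(
        config=config, grid=grid, env=env, occ_raw=occ_raw, occ=occ, truth=truth,
        sco_suitability=sco_P, sco_thresholds=sco_thr,
        sco_membership_raw=sco_mem_raw, sco_membership=sco_mem,
        sdm=sdm_res, sdm_membership=sdm_mem, consensus=cons, composite=comp,
        summary=summary, report=report,
        filter_logs={"sco": sco_log, "sdm": sdm_log},
    )


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write every pipeline artifact to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = _metadata(result.config)
    result.config.to_yaml(out / "config.yaml")
    ddio.write_grid(result.grid, out / "grid.csv", meta)
    ddio.write_env(result.env, out / "environment.csv", meta)
    ddio.write_occurrence(result.occ_raw, out / "occurrence.csv", meta)
    ddio.write_occurrence(result.occ, out / "occurrence_filtered.csv", meta)
    if result.truth is not None:
        ddio.write_truth(result.truth.to_frame(), out / "truth.csv", meta)
    ddio.write_suitability(result.sco_suitability, out / "suitability_sco.csv", meta)
    ddio.write_suitability(result.sdm.suitability, out / "suitability_sdm.csv", meta)
    result.sco_thresholds.rename_axis("species_id").reset_index().to_csv(
        out / "thresholds_sco.csv", index=False, lineterminator="\n")
    threshold_fits_frame(result.sdm.threshold_fits).to_csv(
        out / "thresholds_sdm.csv", index=False, lineterminator="\n")
    ddio.write_membership(result.sco_membership, out / "membership_sco.csv", meta,
                          suit=result.sco_suitability)
    ddio.write_membership(result.sdm_membership, out / "membership_sdm.csv", meta,
                          suit=result.sdm.suitability)
    ddio.write_membership(result.consensus, out / "membership_consensus.csv", meta)
    ddio.write_membership(result.composite, out / "membership_composite.csv", meta)
    ddio.write_summary(result.summary, out / "summary.csv", meta)
    for tag, log in result.filter_logs.items():
        log.to_csv(out / f"filter_log_{tag}.csv", index=False, lineterminator="\n")
    result.report.tests_frame().to_csv(out / "overlap_tests.csv", index=False,
                                       lineterminator="\n")
    result.report.to_json(out / "comparison.json", metadata={str(k): v
                                                             for k, v in meta.items()})
    logger.info("pipeline outputs written to %s", out)
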