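"""CSV readers and writers for all table types.

Conventions: comma-separated, UTF-8, mandatory header row. Lines starting
with ``#`` at the top of a file are metadata (``# key=value``) and are
ignored on read; every writer accepts a ``metadata`` mapping so outputs
carry the seed and parameters that produced them.
"""
from __future__ import annotations

import io as _io
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    EnvTable,
    MembershipMatrix,
    OccurrenceMatrix,
    SiteGrid,
    SuitabilityMatrix,
    ValidationError,
)

SUMMARY_COLUMNS = [
    "site_id", "observed_richness",
    "dark_sco", "dark_sdm", "dark_consensus", "dark_composite",
    "completeness_sco", "completeness_sdm",
    "completeness_consensus", "completeness_composite",
]


def _read_metadata(path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def _write_csv(frame: pd.DataFrame, path, metadata=None, index=False) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        frame.to_csv(fh, index=index, lineterminator="\n")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty file: {path}") from None
    if frame.empty and frame.columns.empty:
        raise ValidationError(f"empty file: {path}")
    return frame


def read_occurrence(path) -> OccurrenceMatrix:
    """Read a site x species 0/1 matrix; first column is ``site_id``."""
    frame = _read_table(path)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: need a site_id column plus >=1 species column")
    sites = tuple(frame.iloc[:, 0].astype(str))
    species = tuple(frame.columns[1:])
    values = frame.iloc[:, 1:].to_numpy()
    if not np.issubdtype(np.asarray(values).dtype, np.number):
        values = frame.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy()
        if np.isnan(values).any():
            i, k = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"{path}: non-numeric incidence at site {sites[i]!r}, "
                f"species {species[k]!r}"
            )
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, k = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: non-binary incidence value {values[i, k]!r} at "
            f"site {sites[i]!r}, species {species[k]!r}"
        )
    return OccurrenceMatrix(sites, species, values.astype(np.int8))


def write_occurrence(occ: OccurrenceMatrix, path, metadata=None) -> None:
    frame = occ.to_frame().reset_index(names="site_id")
    _write_csv(frame, path, metadata)


def read_grid(path) -> SiteGrid:
    frame = _read_table(path)
    required = {"site_id", "x", "y"}
    if not required.issubset(frame.columns):
        raise ValidationError(f"{path}: grid CSV needs columns {sorted(required)}")
    meta = _read_metadata(path)
    cell = float(meta.get("cell_size_km", 1.0))
    return SiteGrid(
        tuple(frame["site_id"].astype(str)),
        frame["x"].to_numpy(float),
        frame["y"].to_numpy(float),
        cell,
    )


def write_grid(grid: SiteGrid, path, metadata=None) -> None:
    meta = dict(metadata or {})
    meta.setdefault("cell_size_km", grid.cell_size)
    _write_csv(grid.to_frame(), path, meta)


def read_env(path) -> EnvTable:
    frame = _read_table(path)
    if "site_id" not in frame.columns:
        raise ValidationError(f"{path}: environment CSV needs a site_id column")
    frame = frame.set_index(frame["site_id"].astype(str)).drop(columns="site_id")
    frame.index.name = "site_id"
    return EnvTable(frame)


def write_env(env: EnvTable, path, metadata=None) -> None:
    frame = env.data.reset_index(names="site_id")
    _write_csv(frame, path, metadata)


def write_suitability(suit: SuitabilityMatrix, path, metadata=None) -> None:
    """Long format: site_id, species_id, method, prob."""
    n_sites, n_species = len(suit.sites), len(suit.species)
    frame = pd.DataFrame({
        "site_id": np.repeat(list(suit.sites), n_species),
        "species_id": np.tile(list(suit.species), n_sites),
        "method": suit.method_tag,
        "prob": suit.values.ravel(),
    })
    _write_csv(frame, path, metadata)


def write_membership(mem: MembershipMatrix, path, metadata=None,
                     suit: SuitabilityMatrix | None = None) -> None:
    """Long format: site_id, species_id, method, member[, prob]."""
    n_sites, n_species = len(mem.sites), len(mem.species)
    frame = pd.DataFrame({
        "site_id": np.repeat(list(mem.sites), n_species),
        "species_id": np.tile(list(mem.species), n_sites),
        "method": mem.method_tag,
        "member": mem.values.ravel().astype(int),
    })
    if suit is not None:
        frame["prob"] = suit.values.ravel()
    _write_csv(frame, path, metadata)


def read_membership(path) -> MembershipMatrix:
    frame = _read_table(path)
    required = {"site_id", "species_id", "method", "member"}
    if not required.issubset(frame.columns):
        raise ValidationError(f"{path}: membership CSV needs columns {sorted(required)}")
    methods = frame["method"].unique()
    if len(methods) != 1:
        raise ValidationError(f"{path}: expected a single method tag, found {list(methods)}")
    wide = frame.pivot(index="site_id", columns="species_id", values="member")
    if wide.isna().any().any():
        raise ValidationError(f"{path}: incomplete site x species coverage")
    # preserve file order of first appearance rather than pivot's sort
    site_order = list(dict.fromkeys(frame["site_id"]))
    species_order = list(dict.fromkeys(frame["species_id"]))
    wide = wide.loc[site_order, species_order]
    return MembershipMatrix(
        tuple(str(s) for s in wide.index),
        tuple(wide.columns),
        wide.to_numpy().astype(bool),
        str(methods[0]),
    )


def write_summary(summary: pd.DataFrame, path, metadata=None) -> None:
    """Write the per-site summary; missing completeness becomes an empty field."""
    frame = summary.copy()
    for col in SUMMARY_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    frame = frame[SUMMARY_COLUMNS]
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        frame.to_csv(fh, index=False, lineterminator="\n", na_rep="")


def read_summary(path) -> pd.DataFrame:
    frame = _read_table(path)
    missing = set(SUMMARY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: summary CSV missing columns {sorted(missing)}")
    return frame


def write_truth(truth_frame: pd.DataFrame, path, metadata=None) -> None:
    _write_csv(truth_frame, path, metadata)
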