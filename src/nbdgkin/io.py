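"""Readers, writers and run configuration.

Interchange formats: long-format CSV for traces (cell_id, t_s, fluor_au,
width_um, length_um), two-column CSV for the extracellular profile (t_s,
conc), JSON for ground truth and posterior draws, YAML for run
configuration.  Times are always seconds in files.  Posterior JSON is
written canonically (sorted keys, fixed separators) so re-serialization of
identical content is byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import InferenceConfig, PosteriorDraws
from .model import CellGeometry, CellTrace, ExternalProfile
from .simulate import ExperimentDesign, GeometryLaw, NoiseSpec, PopulationSpec

__all__ = [
    "SCHEMA_VERSION",
    "read_traces",
    "write_traces",
    "read_profile",
    "write_profile",
    "write_truth",
    "read_truth",
    "write_posterior",
    "read_posterior",
    "RunConfig",
    "read_config",
    "config_hash",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_TRACE_COLUMNS = ["cell_id", "t_s", "fluor_au", "width_um", "length_um"]
_PROFILE_COLUMNS = ["t_s", "conc"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def read_traces(path) -> list[CellTrace]:
    """Read a long-format trace CSV into validated CellTrace objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no trace rows")
    _require_columns(df, _TRACE_COLUMNS, path)
    for col in _TRACE_COLUMNS[1:]:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"{path}: non-numeric values in column {col}")
    if df.duplicated(subset=["cell_id", "t_s"]).any():
        dup = df[df.duplicated(subset=["cell_id", "t_s"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate (cell_id, t_s) pair ({dup.cell_id}, {dup.t_s})"
        )
    traces = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_s")
        geom = CellGeometry(
            width=float(grp["width_um"].iloc[0]),
            length=float(grp["length_um"].iloc[0]),
        )
        traces.append(
            CellTrace(
                cell_id=str(cell_id),
                times=grp["t_s"].to_numpy(dtype=float),
                values=grp["fluor_au"].to_numpy(dtype=float),
                geometry=geom,
            )
        )
    logger.info("read %d traces from %s", len(traces), path)
    return traces


def write_traces(traces: list[CellTrace], path) -> None:
    rows = []
    for tr in traces:
        for t, v in zip(tr.times, tr.values):
            rows.append(
                (tr.cell_id, t, v, tr.geometry.width, tr.geometry.length)
            )
    # %.17g guarantees exact float64 round trips through the CSV
    pd.DataFrame(rows, columns=_TRACE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_profile(path) -> ExternalProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no profile rows")
    _require_columns(df, _PROFILE_COLUMNS, path)
    return ExternalProfile(
        times=df["t_s"].to_numpy(dtype=float),
        conc=df["conc"].to_numpy(dtype=float),
    )


def write_profile(profile: ExternalProfile, path) -> None:
    pd.DataFrame({"t_s": profile.times, "conc": profile.conc}).to_csv(
        path, index=False, float_format="%.17g"
    )


def _canonical_dump(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, sort_keys=True, separators=(",", ":"), allow_nan=False)
        + "\n"
    )


def write_truth(truth: dict, path) -> None:
    """Ground-truth parameters of a synthetic experiment as canonical JSON."""
    _canonical_dump({"schema_version": SCHEMA_VERSION, **truth}, path)


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_posterior(draws: PosteriorDraws, path) -> None:
    """Serialize posterior draws to canonical JSON (round-trips exactly)."""
    obj = {
        "schema_version": SCHEMA_VERSION,
        "seed": draws.seed,
        "cell_ids": list(draws.cell_ids),
        "failed_cells": list(draws.failed_cells),
        "samples": draws.samples.tolist(),
        "n_components": draws.n_components.tolist(),
        "alpha": draws.alpha.tolist(),
        "accept_rate": draws.accept_rate.tolist(),
        "mle_init": draws.mle_init.tolist(),
    }
    _canonical_dump(obj, path)


def read_posterior(path) -> PosteriorDraws:
    obj = json.loads(Path(path).read_text())
    if "schema_version" not in obj:
        raise ValueError(f"{path}: missing schema_version field")
    return PosteriorDraws(
        cell_ids=[str(c) for c in obj["cell_ids"]],
        samples=np.asarray(obj["samples"], dtype=float),
        n_components=np.asarray(obj["n_components"], dtype=np.int64),
        alpha=np.asarray(obj["alpha"], dtype=float),
        accept_rate=np.asarray(obj["accept_rate"], dtype=float),
        mle_init=np.asarray(obj["mle_init"], dtype=float),
        seed=int(obj["seed"]),
        failed_cells=[str(c) for c in obj["failed_cells"]],
    )


@dataclass(frozen=True)
class RunConfig:
    """Assembled run configuration (design / noise / population / inference)."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    population: PopulationSpec | None = None
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    n_cells: int = 40
    seed: int = 0
    log_level: str = "INFO"


def _build(cls, block: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    return cls(**block)


def read_config(path) -> RunConfig:
    """Load a YAML run configuration; absent blocks fall back to defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    pop = None
    if "population" in raw:
        p = raw["population"]
        geometry = _build(GeometryLaw, p.pop("geometry_law", {}))
        pop = PopulationSpec(
            weights=np.asarray(p["weights"], dtype=float),
            means=np.asarray(p["means"], dtype=float),
            covariances=np.asarray(p["covariances"], dtype=float),
            geometry_law=geometry,
        )
    seed = int(raw.get("seed", 0))
    inf_block = dict(raw.get("inference", {}))
    inf_block.setdefault("seed", seed)
    return RunConfig(
        design=_build(ExperimentDesign, dict(raw.get("design", {}))),
        noise=_build(NoiseSpec, dict(raw.get("noise", {}))),
        population=pop,
        inference=_build(InferenceConfig, inf_block),
        n_cells=int(raw.get("n_cells", 40)),
        seed=seed,
        log_level=str(raw.get("log_level", "INFO")),
    )


def config_hash(path) -> str:
    """Short stable digest of a config file, for run logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
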