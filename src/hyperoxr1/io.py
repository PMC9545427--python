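"""Result serialization: CSV tables plus a JSON run manifest."""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .pipeline import SWEEP_COLUMNS, Scenario, VoxelResult

__all__ = ["result_to_frame", "write_table", "read_table", "write_manifest"]


def result_to_frame(scenario: Scenario, result: VoxelResult) -> pd.DataFrame:
    """One-row table with the scenario inputs and every voxel output."""
    row = {
        "tissue_type": scenario.tissue_type,
        "b0": scenario.b0,
        "hct": scenario.hct,
        "oef": scenario.oef,
        "bv": scenario.bv,
        "p_crit": scenario.p_crit,
        "pao2_air": scenario.pao2_air,
        "pao2_ox": scenario.pao2_ox,
        "arterial_fraction": scenario.arterial_fraction,
        **dataclasses.asdict(result),
        "feasible": True,
    }
    return pd.DataFrame([row], columns=SWEEP_COLUMNS)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a results table as CSV with full float precision (round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    # round_trip parser: re-read values bit-identical to what was computed
    return pd.read_csv(path, float_precision="round_trip")


def write_manifest(
    path: str | Path,
    command: str,
    *,
    config: str | None = None,
    identifiers: Mapping[str, Any] | None = None,
    seed: int | None = None,
    outputs: list[str] | None = None,
    coefficient_provenance: str = "user-supplied",
) -> Path:
    """Emit the JSON manifest that accompanies every CLI invocation."""
    manifest = {
        "command": command,
        "config": config,
        "identifiers": dict(identifiers or {}),
        "seed": seed,
        "outputs": outputs or [],
        "coefficient_provenance": coefficient_provenance,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
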