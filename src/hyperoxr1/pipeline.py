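"""Steps 1-4 end to end: scenario evaluation, factorial sweeps, sex contrast.

A :class:`Scenario` holds the five independent variables (B0, hematocrit,
OEF, blood volume, P_crit) plus the gas challenge; :func:`run_scenario`
chains capillary transport, Krogh tissue oxygenation and relaxometry into a
:class:`VoxelResult`, and the voxel ΔR1 is the blood-volume-weighted sum

    ΔR1_voxel = BV*f_A*ΔR1_B,A + (1-BV)*ΔR1_T + BV*(1-f_A)*ΔR1_B,V

with equal arterial/venous fractions (f_A = 1/2) by default.  The arterial
compartment is evaluated at the capillary entrance tensions, the venous
compartment at the exit tensions.

By default the capillary profiles of both gas states use the
saturation-linear decline (SO2(z) = SaO2*(1 - OEF*z/L)) with the same OEF,
matching the closed-form transport equations the model is stated in; the
mass-conserving content-linear mode (absolute extraction fixed at its
normoxic value) is available via ``capillary_mode="content"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields as dataclass_fields
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import krogh, oxygen_transport, relaxometry
from .constants import (
    BloodModelCoefficients,
    OxygenRelaxivityCoefficients,
    PhysiologicalConstants,
)
from .oxygen_transport import InfeasibleExtractionError
from .presets import TissueTypePreset, preset as get_preset

__all__ = [
    "Scenario",
    "VoxelResult",
    "PipelineError",
    "delta_r1_voxel",
    "run_scenario",
    "sweep",
    "sex_comparison",
    "random_scenario",
    "SWEEP_COLUMNS",
]


class PipelineError(RuntimeError):
    """A pipeline step failed; the message names the step."""


class Scenario(BaseModel):
    """Independent variables of one model evaluation."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    b0: float  # T
    hct: float  # fraction
    oef: float  # fraction of arterial content extracted (normoxic)
    bv: float  # voxel blood volume fraction
    p_crit: Optional[float] = None  # mmHg; required whenever a tissue compartment exists
    pao2_air: float = 90.0  # mmHg
    pao2_ox: float = 600.0  # mmHg
    arterial_fraction: float = 0.5  # fraction of blood volume that is arterial
    tissue_type: str = "custom"
    capillary_mode: str = "saturation"  # or "content"
    n_z: int = 51
    n_r: int = 101

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")
        if not 0 < self.hct < 1:
            raise ValueError("hct must lie in (0, 1)")
        if not 0 <= self.oef < 1:
            raise ValueError("oef must lie in [0, 1)")
        if not 0 < self.bv <= 1:
            raise ValueError("bv must lie in (0, 1]")
        if not 0 <= self.arterial_fraction <= 1:
            raise ValueError("arterial_fraction must lie in [0, 1]")
        if self.pao2_air <= 0:
            raise ValueError("pao2_air must be positive")
        if self.pao2_ox < self.pao2_air:
            raise ValueError("pao2_ox must be at least pao2_air")
        if self.capillary_mode not in ("saturation", "content"):
            raise ValueError("capillary_mode must be 'saturation' or 'content'")
        if self.bv < 1.0:
            if self.p_crit is None or np.isnan(self.p_crit):
                raise ValueError("p_crit is required when a tissue compartment exists (bv < 1)")
            if self.p_crit < 0:
                raise ValueError("p_crit must be non-negative")
        return self


@dataclass(frozen=True)
class VoxelResult:
    """Per-compartment ΔR1, weighted voxel ΔR1 and diagnostics."""

    delta_r1_arterial: float  # s-1
    delta_r1_venous: float  # s-1
    delta_r1_tissue: float  # s-1 (0 with nan delta_po2_tissue when no tissue compartment)
    delta_r1_voxel: float  # s-1
    delta_po2_tissue: float  # mmHg
    venous_po2_air: float  # mmHg
    venous_po2_ox: float  # mmHg
    m0: float  # mlO2 ml-1 s-1
    r_t: float  # m
    clamped_fraction: float
    solver_iterations: int


def delta_r1_voxel(
    bv: float,
    d_arterial: float,
    d_tissue: float,
    d_venous: float,
    arterial_fraction: float = 0.5,
) -> float:
    """Blood-volume-weighted voxel ΔR1 (convex combination of compartments)."""
    if not 0 <= bv <= 1:
        raise ValueError("bv must lie in [0, 1]")
    if not 0 <= arterial_fraction <= 1:
        raise ValueError("arterial_fraction must lie in [0, 1]")
    return (bv * arterial_fraction * d_arterial
            + (1.0 - bv) * d_tissue
            + bv * (1.0 - arterial_fraction) * d_venous)


@dataclass(frozen=True)
class _TransportResult:
    """Field-strength-independent (Steps 1-2) outputs of one scenario."""

    venous_po2_air: float
    venous_po2_ox: float
    delta_po2_tissue: float  # nan when bv = 1 (no tissue compartment)
    m0: float
    r_t: float
    clamped_fraction: float
    solver_iterations: int


def _solve_transport(
    scenario: Scenario,
    constants: PhysiologicalConstants,
    voxel_volume: float = 1e-9,
) -> _TransportResult:
    """Steps 1-2: capillary profiles for both gas states, tissue fields, ΔPO2_T."""
    kwargs = dict(n_z=scenario.n_z, mode=scenario.capillary_mode)
    try:
        profile_air = oxygen_transport.capillary_profile(
            scenario.pao2_air, scenario.hct, constants,
            oef=scenario.oef, state_label="air", **kwargs)
        if scenario.capillary_mode == "content":
            # hold the absolute normoxic extraction fixed under hyperoxia
            extraction = scenario.oef * profile_air.content_of_z[0]
            profile_ox = oxygen_transport.capillary_profile(
                scenario.pao2_ox, scenario.hct, constants,
                extraction=extraction, state_label="oxygen", **kwargs)
        else:
            profile_ox = oxygen_transport.capillary_profile(
                scenario.pao2_ox, scenario.hct, constants,
                oef=scenario.oef, state_label="oxygen", **kwargs)
    except InfeasibleExtractionError:
        raise
    except (ValueError, RuntimeError) as exc:
        raise PipelineError(f"step 1 (capillary transport): {exc}") from exc

    if scenario.bv >= 1.0:  # pure blood voxel: no tissue cylinder
        return _TransportResult(
            venous_po2_air=float(profile_air.po2_of_z[-1]),
            venous_po2_ox=float(profile_ox.po2_of_z[-1]),
            delta_po2_tissue=float("nan"), m0=float("nan"), r_t=float("nan"),
            clamped_fraction=0.0, solver_iterations=0)

    try:
        geometry = krogh.capillary_geometry(scenario.bv, constants, voxel_volume)
        sao2_air = oxygen_transport.hill_saturation(
            scenario.pao2_air, constants.p50_tissue, constants.hill_n)
        m0 = krogh.max_consumption_from_oef(
            scenario.oef, scenario.hct, sao2_air, geometry, constants)
        consumption = krogh.ConsumptionModel(
            m0=m0, p_crit=scenario.p_crit, k_diff=constants.k_diff)
        field_air = krogh.tissue_field(profile_air, consumption, geometry, n_r=scenario.n_r)
        field_ox = krogh.tissue_field(profile_ox, consumption, geometry, n_r=scenario.n_r)
        delta = krogh.delta_tissue_po2(field_air, field_ox)
    except (ValueError, RuntimeError) as exc:
        raise PipelineError(f"step 2 (tissue oxygenation): {exc}") from exc

    return _TransportResult(
        venous_po2_air=float(profile_air.po2_of_z[-1]),
        venous_po2_ox=float(profile_ox.po2_of_z[-1]),
        delta_po2_tissue=delta.mean, m0=m0, r_t=geometry.r_t,
        clamped_fraction=max(field_air.clamped_fraction, field_ox.clamped_fraction),
        solver_iterations=max(field_air.max_iterations, field_ox.max_iterations))


def _assemble_result(
    scenario: Scenario,
    transport: _TransportResult,
    constants: PhysiologicalConstants,
    blood_coeffs: BloodModelCoefficients,
    relax_coeffs: OxygenRelaxivityCoefficients,
) -> VoxelResult:
    """Steps 3-4: compartment ΔR1 values and the weighted voxel ΔR1."""
    try:
        d_arterial = relaxometry.delta_r1_blood(
            scenario.pao2_air, scenario.pao2_ox, scenario.hct, scenario.b0,
            blood_coeffs, constants)
        d_venous = relaxometry.delta_r1_blood(
            transport.venous_po2_air, transport.venous_po2_ox, scenario.hct,
            scenario.b0, blood_coeffs, constants)
        if scenario.bv >= 1.0:
            d_tissue = 0.0
        else:
            d_tissue = relaxometry.delta_r1_tissue(
                transport.delta_po2_tissue, scenario.b0, constants.temperature,
                relax_coeffs)
    except ValueError as exc:
        raise PipelineError(f"step 3 (relaxometry): {exc}") from exc

    d_voxel = delta_r1_voxel(scenario.bv, d_arterial, d_tissue, d_venous,
                             scenario.arterial_fraction)
    return VoxelResult(
        delta_r1_arterial=d_arterial, delta_r1_venous=d_venous,
        delta_r1_tissue=d_tissue, delta_r1_voxel=d_voxel,
        delta_po2_tissue=transport.delta_po2_tissue,
        venous_po2_air=transport.venous_po2_air,
        venous_po2_ox=transport.venous_po2_ox,
        m0=transport.m0, r_t=transport.r_t,
        clamped_fraction=transport.clamped_fraction,
        solver_iterations=transport.solver_iterations)


def run_scenario(
    scenario: Scenario,
    constants: PhysiologicalConstants,
    blood_coeffs: BloodModelCoefficients,
    relax_coeffs: OxygenRelaxivityCoefficients,
    voxel_volume: float = 1e-9,
) -> VoxelResult:
    """Evaluate the full four-step pipeline for one scenario (deterministic)."""
    transport = _solve_transport(scenario, constants, voxel_volume)
    return _assemble_result(scenario, transport, constants, blood_coeffs, relax_coeffs)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

_SCENARIO_COLUMNS = ["tissue_type", "b0", "hct", "oef", "bv", "p_crit",
                     "pao2_air", "pao2_ox", "arterial_fraction"]
_RESULT_COLUMNS = [f.name for f in dataclass_fields(VoxelResult)]
SWEEP_COLUMNS = _SCENARIO_COLUMNS + _RESULT_COLUMNS + ["feasible"]


def _grid(bounds: Sequence[float], steps: int) -> np.ndarray:
    lo, hi = bounds
    if lo == hi or steps == 1:
        return np.asarray([lo])
    return np.linspace(lo, hi, steps)


def sweep(
    preset_or_grids: TissueTypePreset | str | Mapping[str, Sequence[float]],
    b0_list: Iterable[float],
    constants: PhysiologicalConstants,
    blood_coeffs: BloodModelCoefficients,
    relax_coeffs: OxygenRelaxivityCoefficients,
    *,
    hct_mode: str = "total",
    steps: int = 5,
    pao2_air: float = 90.0,
    pao2_ox: float = 600.0,
    arterial_fraction: float = 0.5,
    capillary_mode: str = "saturation",
    n_z: int = 51,
    n_r: int = 101,
) -> pd.DataFrame:
    """Evaluate the Cartesian product of uniformly spaced variable grids.

    ``preset_or_grids`` is a tissue-type preset (or its name), or an explicit
    mapping with keys ``hct``, ``oef``, ``bv`` and optionally ``p_crit``.
    Rows appear in deterministic lexicographic order (b0 outermost, then hct,
    oef, bv, p_crit).  Combinations whose extraction is infeasible are kept
    as rows flagged ``feasible=False`` with NaN outputs.
    """
    if isinstance(preset_or_grids, str):
        preset_or_grids = get_preset(preset_or_grids)
    if isinstance(preset_or_grids, TissueTypePreset):
        p = preset_or_grids
        tissue_type = p.name
        grids = {
            "hct": _grid(p.hct_range(hct_mode), steps),
            "oef": _grid(p.oef_range, steps),
            "bv": _grid(p.bv_range, steps),
            "p_crit": (_grid(p.pcrit_range, steps)
                       if p.pcrit_range is not None else np.asarray([np.nan])),
        }
    else:
        tissue_type = "custom"
        grids = {
            "hct": np.asarray(preset_or_grids["hct"], dtype=float),
            "oef": np.asarray(preset_or_grids["oef"], dtype=float),
            "bv": np.asarray(preset_or_grids["bv"], dtype=float),
            "p_crit": np.asarray(preset_or_grids.get("p_crit", [np.nan]), dtype=float),
        }

    b0_values = list(b0_list)
    rows = []
    transport_cache: dict[tuple, _TransportResult | InfeasibleExtractionError] = {}
    for b0, hct, oef, bv, p_crit in itertools.product(
            b0_values, grids["hct"], grids["oef"], grids["bv"], grids["p_crit"]):
        p_crit_val = None if (bv >= 1.0 and np.isnan(p_crit)) else float(p_crit)
        scenario = Scenario(
            b0=float(b0), hct=float(hct), oef=float(oef), bv=float(bv),
            p_crit=p_crit_val, pao2_air=pao2_air, pao2_ox=pao2_ox,
            arterial_fraction=arterial_fraction, tissue_type=tissue_type,
            capillary_mode=capillary_mode, n_z=n_z, n_r=n_r)
        key = (hct, oef, bv, p_crit, pao2_air, pao2_ox, capillary_mode)
        cached = transport_cache.get(key)
        if cached is None:
            try:
                cached = _solve_transport(scenario, constants)
            except InfeasibleExtractionError as exc:
                cached = exc
            transport_cache[key] = cached
        row = dict(tissue_type=tissue_type, b0=b0, hct=hct, oef=oef, bv=bv,
                   p_crit=p_crit if p_crit_val is not None else np.nan,
                   pao2_air=pao2_air, pao2_ox=pao2_ox,
                   arterial_fraction=arterial_fraction)
        if isinstance(cached, InfeasibleExtractionError):
            row.update({name: np.nan for name in _RESULT_COLUMNS})
            row["feasible"] = False
        else:
            result = _assemble_result(scenario, cached, constants, blood_coeffs,
                                      relax_coeffs)
            row.update({name: getattr(result, name) for name in _RESULT_COLUMNS})
            row["feasible"] = True
        rows.append(row)

    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    table.attrs.update({
        "steps": steps, "hct_mode": hct_mode, "capillary_mode": capillary_mode,
        "b0_list": b0_values, "tissue_type": tissue_type,
        "pao2_air": pao2_air, "pao2_ox": pao2_ox,
    })
    return table


def sex_comparison(
    preset_list: Iterable[TissueTypePreset | str],
    b0_list: Iterable[float],
    constants: PhysiologicalConstants,
    blood_coeffs: BloodModelCoefficients,
    relax_coeffs: OxygenRelaxivityCoefficients,
    *,
    steps: int = 5,
    **sweep_kwargs,
) -> pd.DataFrame:
    """Mean voxel ΔR1 over female- vs male-hematocrit sweeps per (preset, B0).

    Returns one row per (tissue type, field strength) with the sweep means
    and their absolute difference; the maximum difference and where it occurs
    are stored in ``.attrs``.
    """
    b0_values = list(b0_list)
    presets = [get_preset(p) if isinstance(p, str) else p for p in preset_list]
    rows = []
    for p in presets:
        tables = {
            mode: sweep(p, b0_values, constants, blood_coeffs, relax_coeffs,
                        hct_mode=mode, steps=steps, **sweep_kwargs)
            for mode in ("female", "male")
        }
        for b0 in b0_values:
            means = {}
            for mode, table in tables.items():
                sub = table[(table["b0"] == b0) & table["feasible"]]
                means[mode] = float(sub["delta_r1_voxel"].mean())
            rows.append(dict(
                tissue_type=p.name, b0=b0,
                mean_delta_r1_female=means["female"],
                mean_delta_r1_male=means["male"],
                abs_difference=abs(means["male"] - means["female"])))
    summary = pd.DataFrame(rows)
    idx = int(summary["abs_difference"].idxmax())
    summary.attrs.update({
        "max_abs_difference": float(summary.loc[idx, "abs_difference"]),
        "max_location_tissue_type": str(summary.loc[idx, "tissue_type"]),
        "max_location_b0": float(summary.loc[idx, "b0"]),
    })
    return summary


def random_scenario(
    seed: int,
    preset_or_name: TissueTypePreset | str,
    b0: float = 1.5,
    hct_mode: str = "total",
    **overrides,
) -> Scenario:
    """Uniform random scenario within a preset's ranges (reproducible by seed)."""
    p = get_preset(preset_or_name) if isinstance(preset_or_name, str) else preset_or_name
    rng = np.random.default_rng(seed)
    hct_lo, hct_hi = p.hct_range(hct_mode)
    values = dict(
        b0=b0,
        hct=float(rng.uniform(hct_lo, hct_hi)),
        oef=float(rng.uniform(*p.oef_range)),
        bv=float(rng.uniform(*p.bv_range)),
        p_crit=(float(rng.uniform(*p.pcrit_range))
                if p.pcrit_range is not None else None),
        tissue_type=p.name,
    )
    values.update(overrides)
    return Scenario(**values)
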