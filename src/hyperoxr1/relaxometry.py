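"""Step 3: longitudinal relaxation rates of blood and tissue.

Blood R1 is a water-fraction-weighted sum of an erythrocyte compartment
(fully oxygenated erythrocyte rate plus a deoxyhemoglobin term proportional
to 1-SO2) and a plasma compartment (plasma rate plus dissolved-oxygen term
proportional to PO2):

    R1_b(PO2) = f_e * (R1_eox + r1_dHb*[Hb]*(1 - SO2(PO2)))
              + (1 - f_e) * (R1_p + r1_pOx*PO2)

with f_e the fraction of blood water residing in erythrocytes.  All four
blood parameters vary linearly with field strength B0.  Tissue ΔR1 is the
dissolved-oxygen relaxivity r1_Ox(B0, T) times the mean tissue PO2 change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    BloodModelCoefficients,
    OxygenRelaxivityCoefficients,
    PhysiologicalConstants,
)
from .oxygen_transport import hill_saturation

__all__ = [
    "FieldParams",
    "CompartmentDeltaR1",
    "erythrocyte_water_fraction",
    "field_params",
    "blood_r1",
    "delta_r1_blood",
    "oxygen_relaxivity",
    "delta_r1_tissue",
]


@dataclass(frozen=True)
class FieldParams:
    """Blood-model parameters evaluated at one field strength."""

    r1_eox: float  # s-1
    r1_p: float  # s-1
    r1_dhb: float  # s-1 L/mmol
    r1_pox: float  # s-1/mmHg
    b0: float  # T


@dataclass(frozen=True)
class CompartmentDeltaR1:
    """Hyperoxia-induced R1 change of each voxel compartment, s-1."""

    arterial: float
    venous: float
    tissue: float


def erythrocyte_water_fraction(hct: float, w_rbc: float = 0.70,
                               w_plasma: float = 0.95) -> float:
    """Fraction of whole-blood water residing in erythrocytes.

    f_e = W_RBC*Hct / (W_RBC*Hct + W_plasma*(1-Hct)); strictly increasing
    bijection of hematocrit on [0, 1].
    """
    if not 0 <= hct <= 1:
        raise ValueError("hct must lie in [0, 1]")
    rbc_water = w_rbc * hct
    return rbc_water / (rbc_water + w_plasma * (1.0 - hct))


def field_params(b0: float, coeffs: BloodModelCoefficients) -> FieldParams:
    """Evaluate the four linear-in-B0 blood parameters at field strength b0."""
    values = {}
    for name, strict in (("r1eox", True), ("r1p", True),
                         ("r1dhb", False), ("r1pox", False)):
        val = getattr(coeffs, f"{name}_beta0") + getattr(coeffs, f"{name}_beta1") * b0
        if val < 0 or (strict and val == 0):
            raise ValueError(f"blood parameter {name} is invalid (negative) at B0={b0} T")
        values[name] = val
    return FieldParams(r1_eox=values["r1eox"], r1_p=values["r1p"],
                       r1_dhb=values["r1dhb"], r1_pox=values["r1pox"], b0=b0)


def blood_r1(
    po2: float,
    hct: float,
    b0: float,
    coeffs: BloodModelCoefficients,
    constants: PhysiologicalConstants,
) -> float:
    """R1 of whole blood at a given oxygen tension, s-1.

    The erythrocyte term uses the blood model's own Hill parameters to convert
    PO2 to saturation; the deoxyhemoglobin contribution scales with the
    corpuscular hemoglobin concentration [Hb] (mmol tetramer/L).
    """
    if po2 < 0:
        raise ValueError("po2 must be non-negative")
    params = field_params(b0, coeffs)
    fe = erythrocyte_water_fraction(hct, constants.w_rbc, constants.w_plasma)
    so2 = hill_saturation(po2, coeffs.p50_blood, coeffs.hill_n_blood)
    erythro = params.r1_eox + params.r1_dhb * constants.hb_molar * (1.0 - so2)
    plasma = params.r1_p + params.r1_pox * po2
    return fe * erythro + (1.0 - fe) * plasma


def delta_r1_blood(
    po2_air: float,
    po2_ox: float,
    hct: float,
    b0: float,
    coeffs: BloodModelCoefficients,
    constants: PhysiologicalConstants,
) -> float:
    """Blood ΔR1 between gas states: R1_b(oxygen) - R1_b(air)."""
    return (blood_r1(po2_ox, hct, b0, coeffs, constants)
            - blood_r1(po2_air, hct, b0, coeffs, constants))


def oxygen_relaxivity(
    b0: float,
    temperature: float,
    coeffs: OxygenRelaxivityCoefficients,
) -> float:
    """Relaxivity of dissolved oxygen, s-1/mmHg, at field b0 and temperature T.

    Lorentzian-plus-temperature form c1/(1 + c2*B0^2) + c3 + c_temp*T;
    decreasing in B0 for physically fitted coefficients.
    """
    if b0 <= 0:
        raise ValueError("b0 must be positive")
    val = coeffs.c1 / (1.0 + coeffs.c2 * b0 * b0) + coeffs.c3 + coeffs.c_temp * temperature
    if val <= 0:
        raise ValueError(f"r1_Ox non-positive at B0={b0} T, T={temperature} degC")
    return val


def delta_r1_tissue(
    delta_po2_t: float,
    b0: float,
    temperature: float,
    coeffs: OxygenRelaxivityCoefficients,
) -> float:
    """Tissue ΔR1 = r1_Ox(B0, T) * ΔPO2_T; linear in the tension change."""
    return oxygen_relaxivity(b0, temperature, coeffs) * delta_po2_t
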