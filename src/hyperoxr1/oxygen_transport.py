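"""Step 1: oxygen saturation, tension and content along the capillary.

Blood oxygen content is the sum of plasma-dissolved and hemoglobin-bound
oxygen, c = alpha_p*PO2 + Hct*c0*SO2, with SO2 tied to PO2 by the Hill
relation.  Total extraction is assumed to rise linearly with distance along
the capillary, so the capillary profile for a physiological state is fully
determined by the arterial tension and the extraction.

Two decline conventions are provided:

``"content"``
    total content declines linearly by the requested absolute extraction;
    PO2/SO2 at each axial position are recovered by numerically inverting the
    content equation together with the Hill curve.  Oxygen mass balance is
    exact by construction.
``"saturation"``
    hemoglobin saturation declines linearly, SO2(z) = SaO2*(1 - OEF*z/L),
    and PO2 follows from the inverse Hill relation.  This is the classical
    closed form; it coincides with the content-linear profile whenever the
    dissolved fraction is negligible (normoxia) but ignores dissolved-oxygen
    depletion under hyperoxia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import PhysiologicalConstants

__all__ = [
    "BloodGasState",
    "CapillaryProfile",
    "InfeasibleExtractionError",
    "hill_saturation",
    "hill_tension",
    "o2_content",
    "invert_content",
    "mean_capillary_saturation",
    "capillary_profile",
]


class InfeasibleExtractionError(ValueError):
    """Requested extraction exceeds the available arterial oxygen content."""


def hill_saturation(po2, p50: float = 37.0, n: float = 2.7):
    """Hemoglobin saturation from oxygen tension via the Hill relation.

    SO2 = PO2^n / (PO2^n + P50^n); strictly increasing in PO2, 0.5 at P50.
    Accepts scalars or arrays.
    """
    if p50 <= 0 or n <= 0:
        raise ValueError("p50 and n must be positive")
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("po2 must be non-negative")
    # (po2/p50)^n / ((po2/p50)^n + 1) is numerically stable for large po2
    ratio = np.power(po2 / p50, n)
    out = ratio / (ratio + 1.0)
    return float(out) if out.ndim == 0 else out


def hill_tension(so2, p50: float = 37.0, n: float = 2.7):
    """Oxygen tension from saturation: exact inverse of :func:`hill_saturation`.

    PO2 = P50 * (SO2/(1-SO2))^(1/n).  SO2=1 has no finite tension.
    """
    if p50 <= 0 or n <= 0:
        raise ValueError("p50 and n must be positive")
    so2 = np.asarray(so2, dtype=float)
    if np.any(so2 < 0) or np.any(so2 >= 1):
        raise ValueError("so2 must lie in [0, 1); saturation 1 has infinite tension")
    out = p50 * np.power(so2 / (1.0 - so2), 1.0 / n)
    return float(out) if out.ndim == 0 else out


def o2_content(po2, so2, hct: float, constants: PhysiologicalConstants):
    """Total blood oxygen concentration, mlO2 per ml blood.

    Dissolved (alpha_p*PO2) plus hemoglobin-bound (Hct*c0*SO2) oxygen.
    """
    if not 0 <= hct <= 1:
        raise ValueError("hct must lie in [0, 1]")
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("po2 must be non-negative")
    out = constants.alpha_p * po2 + hct * constants.c0 * np.asarray(so2, dtype=float)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BloodGasState:
    """Oxygen tension, saturation and total content of one blood sample."""

    po2: float  # mmHg
    so2: float  # fraction
    content: float  # mlO2/ml
    hct: float  # fraction


def invert_content(
    content: float,
    hct: float,
    constants: PhysiologicalConstants,
    p_max: float = 5000.0,
) -> BloodGasState:
    """Solve the content equation jointly with the Hill curve for (PO2, SO2).

    Content is strictly increasing in PO2, so the solution is unique; it is
    found by bracketed root-finding on [0, p_max].
    """
    if content < 0:
        raise ValueError("content must be non-negative")
    if content == 0.0:
        return BloodGasState(po2=0.0, so2=0.0, content=0.0, hct=hct)
    upper = o2_content(p_max, hill_saturation(p_max, constants.p50_tissue, constants.hill_n),
                       hct, constants)
    if content >= upper:
        raise ValueError(
            f"content {content:g} outside solver bracket (max {upper:g} at {p_max} mmHg)"
        )

    def residual(p: float) -> float:
        s = hill_saturation(p, constants.p50_tissue, constants.hill_n)
        return o2_content(p, s, hct, constants) - content

    po2 = brentq(residual, 0.0, p_max, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    so2 = hill_saturation(po2, constants.p50_tissue, constants.hill_n)
    return BloodGasState(po2=float(po2), so2=float(so2),
                         content=float(o2_content(po2, so2, hct, constants)), hct=hct)


def mean_capillary_saturation(sao2: float, oef: float) -> float:
    """Mean capillary SO2 under linear extraction: SaO2*(1 - OEF/2)."""
    return sao2 * (1.0 - oef / 2.0)


@dataclass(frozen=True)
class CapillaryProfile:
    """SO2/PO2/content along the capillary axis for one physiological state."""

    z: np.ndarray  # axial positions, m, 0..L inclusive
    so2_of_z: np.ndarray
    po2_of_z: np.ndarray
    content_of_z: np.ndarray  # mlO2/ml
    state_label: str
    oef_effective: float  # fraction of arterial content extracted
    hct: float = field(default=float("nan"))

    @property
    def arterial(self) -> BloodGasState:
        return BloodGasState(self.po2_of_z[0], self.so2_of_z[0],
                             self.content_of_z[0], self.hct)

    @property
    def venous(self) -> BloodGasState:
        return BloodGasState(self.po2_of_z[-1], self.so2_of_z[-1],
                             self.content_of_z[-1], self.hct)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "z_m": self.z,
            "so2": self.so2_of_z,
            "po2_mmHg": self.po2_of_z,
            "content_mlO2_per_ml": self.content_of_z,
            "state": self.state_label,
        })


def capillary_profile(
    pao2: float,
    hct: float,
    constants: PhysiologicalConstants,
    *,
    oef: float | None = None,
    extraction: float | None = None,
    mode: str = "content",
    n_z: int = 51,
    state_label: str = "air",
) -> CapillaryProfile:
    """Capillary oxygen profile for one gas state.

    Exactly one of ``oef`` (fraction of the *arterial content of this state*)
    or ``extraction`` (absolute content removed over the capillary, mlO2/ml)
    must be given.  ``extraction`` is the natural cross-state input: the
    absolute amount computed from the normoxic OEF can be held fixed under
    hyperoxia (tissue consumption unchanged by the gas challenge).
    """
    if n_z < 2:
        raise ValueError("n_z must be at least 2")
    if (oef is None) == (extraction is None):
        raise ValueError("specify exactly one of oef or extraction")
    if mode not in ("content", "saturation"):
        raise ValueError("mode must be 'content' or 'saturation'")

    sao2 = hill_saturation(pao2, constants.p50_tissue, constants.hill_n)
    ca = o2_content(pao2, sao2, hct, constants)
    if ca <= 0:
        raise InfeasibleExtractionError("arterial oxygen content is zero")
    if extraction is None:
        if not 0 <= oef < 1:
            raise ValueError("oef must lie in [0, 1)")
        oef_frac = oef
        extraction_amount = oef * ca
    else:
        if extraction < 0:
            raise ValueError("extraction must be non-negative")
        if extraction > ca:
            raise InfeasibleExtractionError(
                f"extraction {extraction:g} exceeds arterial content {ca:g} mlO2/ml"
            )
        oef_frac = extraction / ca
        extraction_amount = extraction

    z = np.linspace(0.0, constants.cap_length, n_z)
    frac = z / constants.cap_length

    if extraction_amount == 0.0:
        so2 = np.full(n_z, sao2)
        po2 = np.full(n_z, float(pao2))
        content = np.full(n_z, ca)
    elif mode == "content":
        content = ca - extraction_amount * frac
        po2 = np.empty(n_z)
        so2 = np.empty(n_z)
        po2[0], so2[0] = pao2, sao2
        for i in range(1, n_z):
            state = invert_content(content[i], hct, constants)
            po2[i], so2[i] = state.po2, state.so2
    else:
        so2 = sao2 * (1.0 - oef_frac * frac)
        po2 = hill_tension(so2, constants.p50_tissue, constants.hill_n)
        po2[0] = pao2  # exact arterial endpoint (hill round-trip is identity anyway)
        content = o2_content(po2, so2, hct, constants)

    oef_eff = (content[0] - content[-1]) / content[0]
    return CapillaryProfile(z=z, so2_of_z=so2, po2_of_z=po2, content_of_z=content,
                            state_label=state_label, oef_effective=float(oef_eff),
                            hct=hct)
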