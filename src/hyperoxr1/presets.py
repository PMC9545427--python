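"""Tissue-type presets: published ranges of the five independent variables.

Each preset bundles the OEF, blood-volume, P_crit and hematocrit ranges used
to simulate a tissue class (healthy brain, tumor vascular periphery, hypoxic
tumor at low/high blood volume, normally metabolizing tumor, necrotic core).
The vascular periphery is pure blood (no tissue compartment); the necrotic
core carries a nominal 0.1% blood volume, i.e. effectively no blood
compartment.
"""

from __future__ import annotations

from typing import Optional, Tuple

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = ["TissueTypePreset", "PRESET_NAMES", "preset", "all_presets"]

Range = Tuple[float, float]

HCT_FEMALE: Range = (0.36, 0.48)
HCT_MALE: Range = (0.41, 0.50)
HCT_TOTAL: Range = (0.36, 0.50)


class TissueTypePreset(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    oef_range: Range
    bv_range: Range
    pcrit_range: Optional[Range] = None  # mmHg; None where no tissue compartment
    hct_range_female: Range = HCT_FEMALE
    hct_range_male: Range = HCT_MALE
    hct_range_total: Range = HCT_TOTAL
    has_tissue_compartment: bool = True
    has_blood_compartment: bool = True

    @model_validator(mode="after")
    def _check(self) -> "TissueTypePreset":
        for field in ("oef_range", "bv_range", "hct_range_female",
                      "hct_range_male", "hct_range_total"):
            lo, hi = getattr(self, field)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{field} must satisfy 0 <= lo <= hi <= 1")
        if self.pcrit_range is not None:
            lo, hi = self.pcrit_range
            if not (0.0 <= lo <= hi):
                raise ValueError("pcrit_range must satisfy 0 <= lo <= hi")
        return self

    def midpoint(self, hct_mode: str = "total") -> dict:
        """Midpoint values of every varying range (a representative scenario)."""
        hct_lo, hct_hi = self.hct_range(hct_mode)
        out = {
            "oef": 0.5 * (self.oef_range[0] + self.oef_range[1]),
            "bv": 0.5 * (self.bv_range[0] + self.bv_range[1]),
            "hct": 0.5 * (hct_lo + hct_hi),
        }
        if self.pcrit_range is not None:
            out["p_crit"] = 0.5 * (self.pcrit_range[0] + self.pcrit_range[1])
        return out

    def hct_range(self, mode: str = "total") -> Range:
        try:
            return {
                "female": self.hct_range_female,
                "male": self.hct_range_male,
                "total": self.hct_range_total,
            }[mode]
        except KeyError:
            raise ValueError(
                f"unknown hct mode {mode!r}; choose female, male or total"
            ) from None


_PRESETS = {
    "healthy_brain": TissueTypePreset(
        name="healthy_brain",
        oef_range=(0.31, 0.37),
        bv_range=(0.02, 0.07),
        pcrit_range=(1.0, 4.0),
    ),
    "vascular_periphery": TissueTypePreset(
        name="vascular_periphery",
        oef_range=(0.24, 0.44),
        bv_range=(1.0, 1.0),
        pcrit_range=None,
        has_tissue_compartment=False,
    ),
    "hypoxic_low_bv": TissueTypePreset(
        name="hypoxic_low_bv",
        oef_range=(0.02, 0.2),
        bv_range=(0.047, 0.059),
        pcrit_range=(0.5, 2.0),
    ),
    "hypoxic_high_bv": TissueTypePreset(
        name="hypoxic_high_bv",
        oef_range=(0.02, 0.2),
        bv_range=(0.09, 0.17),
        pcrit_range=(0.5, 2.0),
    ),
    "normal_metabolism": TissueTypePreset(
        name="normal_metabolism",
        oef_range=(0.02, 0.05),
        bv_range=(0.047, 0.059),
        pcrit_range=(0.5, 2.0),
    ),
    "necrotic": TissueTypePreset(
        name="necrotic",
        oef_range=(0.02, 0.05),
        bv_range=(0.001, 0.001),
        pcrit_range=(0.5, 2.0),
        has_blood_compartment=False,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> TissueTypePreset:
    """Look up a tissue-type preset by name."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown tissue type {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None


def all_presets() -> dict[str, TissueTypePreset]:
    return dict(_PRESETS)
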