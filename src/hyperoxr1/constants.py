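"""Physical constants and empirically fitted coefficient sets.

The tissue/transport constants (hemoglobin dissociation, solubilities,
diffusivity, capillary geometry) ship with literature defaults and can be
overridden from a JSON configuration document.  The blood-R1 and
oxygen-relaxivity coefficients are *fits to relaxometry data published
elsewhere*: they must be transcribed by the user from the original blood-model
and oxygen-relaxivity publications.  A synthetic placeholder set with the
right orders of magnitude is provided for testing only and is never loaded
silently.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "PhysiologicalConstants",
    "BloodModelCoefficients",
    "OxygenRelaxivityCoefficients",
    "ConfigError",
    "MissingCoefficientsError",
    "load_constants",
    "load_blood_coefficients",
    "load_relaxivity_coefficients",
    "placeholder_blood_coefficients",
    "placeholder_relaxivity_coefficients",
    "config_schema",
]


class ConfigError(ValueError):
    """A configuration document could not be parsed or validated."""


class MissingCoefficientsError(ConfigError):
    """Required fitted coefficients were not supplied."""


TRANSCRIPTION_HINT = (
    "Blood-model and oxygen-relaxivity coefficients are empirical fits and are "
    "not bundled with this package. Transcribe the eight beta values (intercept "
    "and slope on B0 for R1eox, R1p, r1dHb, r1pOx) from the original blood R1 "
    "publication, and c1, c2, c3, c_temp from the oxygen-relaxivity "
    "publication, into the 'blood_coefficients' and 'relaxivity_coefficients' "
    "sections of your config. For testing only, placeholder_blood_coefficients() "
    "/ placeholder_relaxivity_coefficients() (CLI: --placeholder-coeffs) supply "
    "a synthetic, physically plausible set."
)


class PhysiologicalConstants(BaseModel):
    """Literature constants of the oxygen-transport and tissue model.

    Units are fixed: pressures mmHg, lengths m, solubilities mlO2·ml⁻¹·mmHg⁻¹,
    diffusivity m²·s⁻¹, velocity m·s⁻¹, temperature °C.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    p50_tissue: float = 37.0  # hemoglobin half-saturation tension, mmHg
    hill_n: float = 2.7  # Hill exponent, unitless
    alpha_p: float = 3.1e-5  # plasma O2 solubility
    c_hb: float = 1.36  # Huffner factor, mlO2 per g hemoglobin
    c0: float = 0.5  # O2 capacity per unit RBC volume at full saturation
    hb_molar: float = 5.15  # MCHC, mmol tetramer / L
    hb_mass: float = 0.43  # MCHC, g / mL
    alpha_t: float = 2.8e-5  # tissue O2 solubility
    d_t: float = 2.41e-9  # tissue O2 diffusivity
    cap_length: float = 0.001  # capillary length L, m
    cap_radius: float = 3.5e-6  # capillary radius R_c, m
    cap_velocity: float = 0.00079  # capillary blood velocity v, m/s
    w_rbc: float = 0.70  # erythrocyte water volume fraction
    w_plasma: float = 0.95  # plasma water volume fraction
    temperature: float = 37.0  # degrees C

    @property
    def k_diff(self) -> float:
        """Krogh diffusion constant K = D_T * a_T."""
        return self.d_t * self.alpha_t

    @model_validator(mode="after")
    def _check(self) -> "PhysiologicalConstants":
        for name in self.__class__.model_fields:
            if getattr(self, name) <= 0:
                raise ValueError(f"constant '{name}' must be strictly positive")
        if self.hill_n <= 1:
            raise ValueError("hill_n must exceed 1")
        for name in ("w_rbc", "w_plasma"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"'{name}' must lie in (0, 1]")
        if self.cap_radius >= self.cap_length:
            raise ValueError("cap_radius must be smaller than cap_length")
        # The RBC oxygen capacity is nominally the Huffner factor times the
        # corpuscular hemoglobin mass concentration, but the adopted c0 is a
        # rounded literature value; surface the discrepancy without failing.
        product = self.c_hb * self.hb_mass
        if abs(product - self.c0) / self.c0 > 0.01:
            logger.info(
                "c0=%g differs from c_hb*hb_mass=%g; keeping the configured c0",
                self.c0,
                product,
            )
        return self


class BloodModelCoefficients(BaseModel):
    """Linear-in-B0 coefficients of the two-compartment blood R1 model.

    Each blood parameter p is evaluated as p(B0) = beta0 + beta1*B0:
    ``r1eox`` (fully oxygenated erythrocyte R1, s⁻¹), ``r1p`` (plasma R1, s⁻¹),
    ``r1dhb`` (deoxyhemoglobin molar relaxivity, s⁻¹·L·mmol⁻¹) and ``r1pox``
    (dissolved-O2 relaxivity in plasma, s⁻¹·mmHg⁻¹).  The blood model carries
    its own hemoglobin dissociation parameters since the original fit need not
    share the tissue model's P50.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    r1eox_beta0: float
    r1eox_beta1: float
    r1p_beta0: float
    r1p_beta1: float
    r1dhb_beta0: float
    r1dhb_beta1: float
    r1pox_beta0: float
    r1pox_beta1: float
    p50_blood: float = 37.0
    hill_n_blood: float = 2.7

    @model_validator(mode="after")
    def _check(self) -> "BloodModelCoefficients":
        if self.p50_blood <= 0 or self.hill_n_blood <= 0:
            raise ValueError("p50_blood and hill_n_blood must be positive")
        # linear functions: positivity on [1.5, 7] T follows from the endpoints.
        # Compartment rates must stay strictly positive; the two relaxivities
        # may be zero (degenerate/no-effect settings) but never negative.
        for name, strict in (("r1eox", True), ("r1p", True),
                             ("r1dhb", False), ("r1pox", False)):
            b0_, b1_ = getattr(self, f"{name}_beta0"), getattr(self, f"{name}_beta1")
            for b in (1.5, 7.0):
                val = b0_ + b1_ * b
                if val < 0 or (strict and val == 0):
                    raise ValueError(
                        f"fitted {name}(B0) is {'non-positive' if strict else 'negative'} "
                        f"at B0={b} T; check the transcribed coefficients"
                    )
        return self


class OxygenRelaxivityCoefficients(BaseModel):
    """Lorentzian-plus-temperature fit of the dissolved-oxygen relaxivity.

    r1_Ox(B0, T) = c1/(1 + c2*B0²) + c3 + c_temp*T, in s⁻¹·mmHg⁻¹ with B0 in
    tesla and T in °C.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    c1: float
    c2: float
    c3: float
    c_temp: float

    @model_validator(mode="after")
    def _check(self) -> "OxygenRelaxivityCoefficients":
        prev = None
        for b in (1.5, 3.0, 4.7, 7.0):
            val = self.c1 / (1.0 + self.c2 * b * b) + self.c3 + self.c_temp * 37.0
            if val <= 0:
                raise ValueError(f"r1_Ox non-positive at B0={b} T, 37 degC")
            if prev is not None and val > prev:
                raise ValueError("r1_Ox must be non-increasing in B0 on [1.5, 7] T")
            prev = val
        return self


def _read_document(source: Mapping[str, Any] | str | Path) -> Mapping[str, Any]:
    """Accept a mapping, a path to a JSON file, or a JSON string."""
    if isinstance(source, Mapping):
        return source
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file()):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:  # pragma: no cover - defensive
        raise ConfigError(f"unsupported config source type {type(source)!r}")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed configuration document: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a JSON object")
    return doc


def _section(doc: Mapping[str, Any], name: str) -> Mapping[str, Any]:
    sub = doc.get(name)
    if isinstance(sub, Mapping):
        return sub
    return doc


def load_constants(source: Mapping[str, Any] | str | Path | None = None) -> PhysiologicalConstants:
    """Load physiological constants, falling back to literature defaults.

    ``source`` may be a dict, a JSON string, or a path to a JSON file; a
    ``constants`` section is honored if present.  ``None`` or an empty
    document yields the full default set.
    """
    if source is None:
        return PhysiologicalConstants()
    doc = _section(_read_document(source), "constants")
    try:
        return PhysiologicalConstants(**doc)
    except ValidationError as exc:
        raise ConfigError(f"invalid constants: {_summarize(exc)}") from exc


def load_blood_coefficients(source: Mapping[str, Any] | str | Path) -> BloodModelCoefficients:
    """Load blood-model coefficients; all eight beta values are required."""
    doc = _section(_read_document(source), "blood_coefficients")
    try:
        return BloodModelCoefficients(**doc)
    except ValidationError as exc:
        if any(err.get("type") == "missing" for err in exc.errors()):
            raise MissingCoefficientsError(
                f"missing blood-model coefficients ({_summarize(exc)}). "
                + TRANSCRIPTION_HINT
            ) from exc
        raise ConfigError(f"invalid blood coefficients: {_summarize(exc)}") from exc


def load_relaxivity_coefficients(source: Mapping[str, Any] | str | Path) -> OxygenRelaxivityCoefficients:
    """Load oxygen-relaxivity coefficients; c1..c_temp are required."""
    doc = _section(_read_document(source), "relaxivity_coefficients")
    try:
        return OxygenRelaxivityCoefficients(**doc)
    except ValidationError as exc:
        if any(err.get("type") == "missing" for err in exc.errors()):
            raise MissingCoefficientsError(
                f"missing relaxivity coefficients ({_summarize(exc)}). "
                + TRANSCRIPTION_HINT
            ) from exc
        raise ConfigError(f"invalid relaxivity coefficients: {_summarize(exc)}") from exc


def _summarize(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<document>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


# ---------------------------------------------------------------------------
# Synthetic placeholder coefficient sets (testing only)
# ---------------------------------------------------------------------------

#: Synthetic stand-in for the blood-model fit: magnitudes follow published
#: whole-blood/plasma R1 values (R1 decreasing with B0) and deoxyhemoglobin
#: relaxivities of roughly 0.11 s-1/mM at 1.5T and 0.35 s-1/mM at 4.7T.
#: NOT the original fitted values - do not use for science outputs.
_PLACEHOLDER_BLOOD = dict(
    r1eox_beta0=1.70, r1eox_beta1=-0.20,
    r1p_beta0=0.75, r1p_beta1=-0.06,
    r1dhb_beta0=0.0, r1dhb_beta1=0.075,
    r1pox_beta0=4.2e-4, r1pox_beta1=-3.0e-5,
    p50_blood=37.0, hill_n_blood=2.7,
)

#: Synthetic stand-in for the oxygen-relaxivity fit: r1_Ox ~ 2e-4 s-1/mmHg at
#: 1.5T / 37 degC, strictly decreasing with B0. NOT the original fitted values.
_PLACEHOLDER_RELAXIVITY = dict(c1=2.8e-4, c2=0.25, c3=6.0e-5, c_temp=-1.0e-6)


def placeholder_blood_coefficients() -> BloodModelCoefficients:
    """Synthetic blood-model coefficients for testing; logs a warning."""
    logger.warning(
        "Using SYNTHETIC placeholder blood-model coefficients - for testing "
        "only, not the published fit. %s", TRANSCRIPTION_HINT,
    )
    return BloodModelCoefficients(**_PLACEHOLDER_BLOOD)


def placeholder_relaxivity_coefficients() -> OxygenRelaxivityCoefficients:
    """Synthetic oxygen-relaxivity coefficients for testing; logs a warning."""
    logger.warning(
        "Using SYNTHETIC placeholder oxygen-relaxivity coefficients - for "
        "testing only, not the published fit.",
    )
    return OxygenRelaxivityCoefficients(**_PLACEHOLDER_RELAXIVITY)


def config_schema() -> dict:
    """JSON schema of the full configuration document (all sections)."""
    return {
        "type": "object",
        "properties": {
            "constants": PhysiologicalConstants.model_json_schema(),
            "blood_coefficients": BloodModelCoefficients.model_json_schema(),
            "relaxivity_coefficients": OxygenRelaxivityCoefficients.model_json_schema(),
            "scenario": {"type": "object"},
        },
    }
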