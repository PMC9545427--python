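# Methods

`hyperoxr1` predicts the change in the longitudinal relaxation rate R1
(ΔR1, s⁻¹) that a hyperoxic gas challenge induces in an imaging voxel, as
used in oxygen-enhanced MRI (OE-MRI) of tumors, brain and other tissues.
The voxel is modelled as three compartments — arterial blood, venous blood
and tissue — evaluated in four steps.

## Model

**Step 1 — capillary oxygen transport.** Blood oxygen content combines
dissolved and hemoglobin-bound oxygen,

    c = α_p·PO₂ + Hct·c₀·SO₂,

with SO₂ tied to PO₂ by the Hill curve SO₂ = PO₂ⁿ/(PO₂ⁿ + P50ⁿ). The oxygen
extraction fraction OEF = (CaO₂ − CvO₂)/CaO₂ sets the venous endpoint, and
extraction is assumed to rise linearly along the capillary, so the mean
capillary saturation is SaO₂·(1 − OEF/2). Arterial tension is a user input;
the default challenge raises PaO₂ from 90 to 600 mmHg.

Two axial-decline conventions are implemented:

* `saturation` (default in the pipeline): SO₂(z) = SaO₂·(1 − OEF·z/L), with
  PO₂(z) from the inverse Hill relation and the *same* OEF applied in both
  gas states. This is the closed form the transport model is usually stated
  in; it treats OEF as a saturation-extraction fraction.
* `content`: total content declines linearly by a fixed absolute amount
  (the normoxic extraction OEF·CaO₂(air), held fixed under hyperoxia since
  tissue consumption does not change with the inhaled gas); PO₂/SO₂ are
  recovered by numerically inverting the content equation. Oxygen mass is
  conserved to machine precision by construction.

The two coincide whenever dissolved oxygen is negligible (normoxia). Under
hyperoxia they differ materially at low OEF: the content-linear rule spends
the extraction on dissolved oxygen first, leaving venous PO₂ (and hence the
tissue tension change) several hundred mmHg high, which makes low-OEF
necrotic tissue the *strongest* ΔR1 responder — contradicting both the
saturation-linear closed form and the reported OE-MRI orderings this class
of model is meant to reproduce. The saturation-linear rule is therefore the
pipeline default; the content-linear mode remains available
(`capillary_mode="content"`) and carries the exact mass-balance guarantees.

**Step 2 — tissue oxygenation (Krogh cylinder).** Each capillary (radius
R_c = 3.5 µm, length L = 1 mm) supplies a coaxial tissue cylinder of radius
R_t. Arranging N_cap parallel, unbranched, evenly spaced capillaries on a
√N×√N cross-sectional grid of a voxel with blood volume fraction BV gives
the voxel-size-independent relation

    R_t = (R_c/2)·√(π/BV).

(The printed form of this geometry in the source literature is dimensionally
inconsistent; the grid reading above is the only one compatible with evenly
spaced parallel capillaries. With it, the published R_t range 1.07–4.43×10⁻⁵ m
is *not* recovered from the published BV ranges — we compute 7.5×10⁻⁶ to
9.8×10⁻⁵ m — so computed R_t values are reported alongside, never asserted
against, the published range.)

The maximum consumption rate M₀ follows from steady-state mass balance in
the normoxic state — delivered oxygen per capillary equals annulus
consumption:

    v·π·R_c²·Hct·c₀·SaO₂·OEF = M₀·π·(R_t² − R_c²)·L.

(Again the printed companion formula omits R_c² and uses the Hüffner factor
where the volumetric capacity c₀ belongs; the mass-balance form is used, and
the resulting M₀ range is reported next to, not asserted against, the
published 1.2×10⁻⁵–3.5×10⁻⁴ mlO₂·ml⁻¹·s⁻¹.)

For uniform consumption M the steady radial profile is the Krogh–Erlang
solution

    PO₂(r) = P_cap + (M/4K)(r² − R_c²) − (M·R_t²/2K)·ln(r/R_c),

with K = D_T·α_T the Krogh diffusion constant and zero flux at R_t.
Oxygen-dependent consumption uses Michaelis–Menten kinetics
M(PO₂) = M₀·PO₂/(PO₂ + P_crit). Because the closed form is exact only for
uniform M, each axial slice carries one *effective* rate, found by fixed
point: start at M₀, evaluate the profile, set M = M(mean slice PO₂), repeat
until the mean changes by < 10⁻⁶ mmHg (damped 0.5 update on oscillation,
error after 100 iterations). Negative closed-form tensions are clamped at 0
and the clamped volume fraction reported. An independent two-point
boundary-value solve with fully spatially varying M(PO₂(r)) serves as the
test oracle; across random draws from every tissue preset the slice solver
agrees with it to well under 0.5 mmHg in mean tension (typically < 0.01),
because tissue PO₂ stays far above P_crit in these regimes.

**Step 3 — relaxometry.** Blood R1 is a two-compartment water-fraction
average,

    R1_b(PO₂) = f_e·(R1_eox + r1_dHb·[Hb]·(1 − SO₂)) + (1 − f_e)·(R1_p + r1_pOx·PO₂),

with f_e(Hct) = W_RBC·Hct/(W_RBC·Hct + W_plasma·(1−Hct)) the erythrocyte
water fraction and all four parameters linear in B0 (β₀ + β₁·B0). The
arterial compartment is evaluated at the capillary-entrance tensions, the
venous compartment at the exit tensions. Tissue ΔR1 is the dissolved-oxygen
relaxivity times the mean tissue tension change, ΔR1_T = r1_Ox(B0, T)·ΔPO₂_T,
with the Lorentzian-plus-temperature form
r1_Ox = c₁/(1 + c₂·B0²) + c₃ + c_T·T evaluated at 37 °C.

**Step 4 — voxel aggregation.**

    ΔR1_voxel = BV·f_A·ΔR1_B,A + (1 − BV)·ΔR1_T + BV·(1 − f_A)·ΔR1_B,V,

with the arterial fraction f_A = 0.5 by default (equal arterial and venous
blood volumes; exposed as a parameter because the equal split is a known
simplification).

## Parameters

Defaults (all overridable via JSON config, fixed units):

| parameter | default | units | meaning |
|---|---|---|---|
| P50 (tissue) | 37 | mmHg | hemoglobin half-saturation tension |
| n | 2.7 | – | Hill exponent |
| α_p | 3.1×10⁻⁵ | mlO₂·ml⁻¹·mmHg⁻¹ | plasma O₂ solubility |
| c₀ | 0.5 | mlO₂·ml⁻¹ | RBC O₂ capacity at full saturation |
| [Hb] | 5.15 | mmol/L | corpuscular hemoglobin (molar) |
| α_T | 2.8×10⁻⁵ | mlO₂·ml⁻¹·mmHg⁻¹ | tissue O₂ solubility |
| D_T | 2.41×10⁻⁹ | m²·s⁻¹ | tissue O₂ diffusivity |
| L, R_c | 10⁻³, 3.5×10⁻⁶ | m | capillary length, radius |
| v | 7.9×10⁻⁴ | m·s⁻¹ | capillary blood velocity |
| W_RBC, W_plasma | 0.70, 0.95 | – | water volume fractions |
| PaO₂ air→O₂ | 90 → 600 | mmHg | default gas challenge |

c₀ is stored independently rather than recomputed from the Hüffner factor
times the corpuscular hemoglobin mass concentration (1.36 × 0.43 = 0.585,
not 0.5); the adopted literature value is 0.5 and the discrepancy is logged,
not silently reconciled. Two P50 values are carried: the tissue-model P50
above and a separately configurable blood-model P50, since the blood R1 fit
need not share the tissue dissociation curve.

Tissue-type presets bundle published ranges of OEF, BV, P_crit and
hematocrit (female 0.36–0.48, male 0.41–0.50, total 0.36–0.50): healthy
brain (OEF 0.31–0.37, BV 0.02–0.07, P_crit 1–4), tumor vascular periphery
(OEF 0.24–0.44, BV 1.0, no tissue compartment), hypoxic tumor at low
(0.047–0.059) and high (0.09–0.17) BV with OEF 0.02–0.2, normally
metabolizing tumor (OEF 0.02–0.05, BV 0.047–0.059) and necrotic core
(BV 0.001, OEF 0.02–0.05). Tumor presets use P_crit 0.5–2 mmHg.

## Fitted coefficients

The blood-model βs and the r1_Ox constants are empirical fits published in
companion relaxometry papers; they are **not bundled** and must be
transcribed into the config by the user. The package ships a clearly
labelled *synthetic placeholder* set for testing: magnitudes follow
published whole-blood/plasma R1 values (decreasing with B0), a
deoxyhemoglobin relaxivity interpolating ≈0.11 s⁻¹/mM at 1.5 T and
≈0.35 s⁻¹/mM at 4.7 T, and r1_Ox ≈ 2×10⁻⁴ s⁻¹/mmHg at 1.5 T/37 °C
decreasing with field. Every CLI run records whether coefficients were
user-supplied or placeholders, and placeholder use logs a warning. All
quantitative ΔR1 outputs are conditional on the transcription; the
*structural* behaviors (signs, monotonicities, tissue-type orderings)
hold for any physically plausible set.

## Numerical choices

* Default grids: 51 axial × 101 radial points, uniform; volume weights
  ∝ r·Δr·Δz (trapezoid). N_cap is kept continuous to avoid discretization
  steps in sweeps.
* Content inversion uses bracketed Brent root-finding on [0, 5000] mmHg with
  xtol 10⁻¹² (the content equation is strictly increasing in PO₂, so the
  solution is unique).
* The per-slice fixed point is vectorized across all axial slices with the
  identical update rule as the scalar solver (cross-checked to 10⁻¹⁰ in the
  tests); Steps 1–2 are cached per physiological combination during sweeps
  because they do not depend on B0.
* Sweeps default to 5 uniformly spaced points per varying range (the
  factorial design's resolution is a free choice; 5 keeps the full
  six-preset × four-field sex comparison at ~10 s on one core). Rows whose
  extraction would be infeasible are flagged, not fatal.
* Degenerate voxels: BV = 1 skips the tissue path (tissue ΔR1 reported as 0
  with NaN ΔPO₂_T and zero weight); BV = 0 is rejected by the geometry
  (there is no capillary to supply the tissue) — the tissue-only limit is
  available through the aggregation step directly.

## What the tests do and do not show

The test suite exercises frozen arithmetic examples, exact inverses,
conservation laws, independent numerical oracles (boundary-value solve,
bisection inversion) and structural/qualitative properties (venous ΔR1 < 0
below full saturation, periphery > necrotic > hypoxic-core voxel ΔR1 at
1.5 T midpoints, sex contrast maximal in the blood-dominated periphery).
Passing them shows the implementation is faithful to the stated model and
numerically sound — not that the model predicts any particular patient's
ΔR1: real tissue violates several Krogh assumptions (branched, tortuous
capillaries, axial diffusion, non-steady state), the equal arterial/venous
split is a simplification, and quantitative outputs depend on transcribed
coefficients.

## Known limitations

No Bohr/Haldane or 2,3-DPG shifts of the dissociation curve; no R2/R2*
modelling; no intravascular resistance or axial tissue diffusion; steady
state only; temperature fixed at 37 °C in tissue context (exposed for the
relaxivity-vs-temperature family); the published R_t and M₀ ranges are not
reproducible from the published geometry equations (see above) and are
reported as a logged comparison only.
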