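# hyperoxr1

Predicts the change in the longitudinal relaxation rate R1 (ΔR1 = Δ(1/T1),
s⁻¹) that breathing supplemental oxygen induces in an imaging voxel — the
quantity measured by oxygen-enhanced MRI (OE-MRI) to probe tumor hypoxia,
brain oxygenation and lung disease. It is written for OE-MRI researchers who
want to estimate the ΔR1 expected for a tissue of interest, or to study how
field strength, hematocrit, oxygen extraction and blood volume confound the
measured signal.

## Model

A voxel is three compartments — arterial blood, venous blood, tissue —
evaluated in four steps:

1. **Capillary transport.** Blood O₂ content c = α_p·PO₂ + Hct·c₀·SO₂, with
   SO₂ = PO₂ⁿ/(PO₂ⁿ + P50ⁿ) (Hill). Extraction rises linearly along the
   capillary: SO₂(z) = SaO₂·(1 − OEF·z/L). The challenge raises arterial
   PO₂ from 90 to 600 mmHg by default.
2. **Tissue oxygenation.** Each capillary supplies a Krogh cylinder of
   radius R_t = (R_c/2)·√(π/BV); consumption is Michaelis–Menten,
   M(PO₂) = M₀·PO₂/(PO₂+P_crit), with M₀ fixed by normoxic mass balance
   from the OEF; the radial profile is the Krogh–Erlang solution
   PO₂(r) = P_cap + (M/4K)(r²−R_c²) − (M·R_t²/2K)·ln(r/R_c).
3. **Relaxometry.** Blood: R1_b = f_e·(R1_eox + r1_dHb·[Hb]·(1−SO₂)) +
   (1−f_e)·(R1_p + r1_pOx·PO₂), all four parameters linear in B0.
   Tissue: ΔR1_T = r1_Ox(B0,T)·ΔPO₂_T with
   r1_Ox = c₁/(1+c₂·B0²) + c₃ + c_T·T.
4. **Voxel aggregation.**
   ΔR1_voxel = (BV/2)·ΔR1_B,A + (1−BV)·ΔR1_T + (BV/2)·ΔR1_B,V.

Because deoxyhemoglobin is paramagnetic and oxygenation removes it, venous
blood shows a *negative* ΔR1 while tissue and arterial blood show positive
changes — the model quantifies how their blood-volume-weighted sum behaves.
See `docs/methods.md` for assumptions, parameter tables and numerical
details.

The fitted blood-model and oxygen-relaxivity coefficients are published
elsewhere and must be transcribed into a config file (see
`examples/config.example.json`); a clearly labelled synthetic placeholder
set ships for testing (`--placeholder-coeffs`).

## Worked example

```python
import hyperoxr1 as hx

constants = hx.PhysiologicalConstants()          # literature defaults
blood = hx.placeholder_blood_coefficients()      # synthetic, testing only
relax = hx.placeholder_relaxivity_coefficients()

for name in ("vascular_periphery", "necrotic", "hypoxic_high_bv", "healthy_brain"):
    scenario = hx.Scenario(b0=1.5, tissue_type=name, **hx.preset(name).midpoint())
    r = hx.run_scenario(scenario, constants, blood, relax)
    print(f"{name:20s} dR1_voxel={r.delta_r1_voxel:+.4f}  "
          f"A={r.delta_r1_arterial:+.4f} V={r.delta_r1_venous:+.4f} "
          f"T={r.delta_r1_tissue:+.4f} s^-1")
```

prints (placeholder coefficients, 1.5 T, 90→600 mmHg challenge):

```
vascular_periphery   dR1_voxel=+0.0477  A=+0.1058 V=-0.0103 T=+0.0000 s^-1
necrotic             dR1_voxel=+0.0215  A=+0.1058 V=-0.0052 T=+0.0215 s^-1
hypoxic_high_bv      dR1_voxel=+0.0154  A=+0.1058 V=-0.0114 T=+0.0107 s^-1
healthy_brain        dR1_voxel=+0.0068  A=+0.1058 V=-0.0103 T=+0.0049 s^-1
```

The blood-rich vascular periphery responds most, necrotic tissue (almost no
blood, little consumption, large tissue ΔPO₂) sits in between, the hypoxic
tumor core responds less, and healthy brain — high OEF, low blood volume —
barely responds. Venous ΔR1 is negative everywhere: deoxyhemoglobin loss
dominates dissolved oxygen below full saturation.

From the shell:

```sh
hyperoxr1 run --preset necrotic --b0 1.5 --placeholder-coeffs --out voxel.csv
hyperoxr1 sweep --preset vascular_periphery --b0 1.5,3,4.7,7 \
    --sex-comparison --placeholder-coeffs --out sweep.csv
hyperoxr1 presets        # print tissue-type ranges
hyperoxr1 validate       # run invariant self-checks
```

Each run writes a CSV plus a `.manifest.json` recording inputs, package
version and coefficient provenance.

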