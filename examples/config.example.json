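{
  "_comment": "Example configuration. The 'constants' section may be partial (omitted keys fall back to literature defaults). The blood_coefficients and relaxivity_coefficients values below are the SYNTHETIC TEST PLACEHOLDERS shipped with the package - replace them with values transcribed from the original blood-R1 and oxygen-relaxivity publications before producing science outputs. Units: pressures mmHg, lengths m, relaxation rates s^-1, r1dHb s^-1 L/mmol, r1pOx and r1_Ox s^-1/mmHg, B0 tesla, temperature degC.",
  "constants": {
    "p50_tissue": 37.0,
    "hill_n": 2.7
  },
  "blood_coefficients": {
    "r1eox_beta0": 1.7,
    "r1eox_beta1": -0.2,
    "r1p_beta0": 0.75,
    "r1p_beta1": -0.06,
    "r1dhb_beta0": 0.0,
    "r1dhb_beta1": 0.075,
    "r1pox_beta0": 0.00042,
    "r1pox_beta1": -0.00003,
    "p50_blood": 37.0,
    "hill_n_blood": 2.7
  },
  "relaxivity_coefficients": {
    "c1": 0.00028,
    "c2": 0.25,
    "c3": 0.00006,
    "c_temp": -0.000001
  },
  "scenario": {
    "b0": 1.5,
    "hct": 0.42,
    "oef": 0.34,
    "bv": 0.05,
    "p_crit": 2.0,
    "pao2_air": 90.0,
    "pao2_ox": 600.0
  }
}
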