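{
  "k1": "5.7e-6 mol/L/s",
  "k2": 1.5e9,
  "k2_sod": "2.8e4 /s",
  "k1_prime": "12e-6 mol/L/s",
  "vmax_ahp": "6.6e-4 mol/L/s",
  "km_ahp": "1.2e-6 M",
  "vmax_cat": "4.9e-1 mol/L/s",
  "km_cat": "5.9e-3 M",
  "kdiff": "70 /s",
  "vin": "3.2e-15 L",
  "permeability": 1.6e-3,
  "area": 1.41e-7
}
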