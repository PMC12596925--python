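{
  "k_TM": 1.75e-05,
  "substrate_init": 0.0002,
  "oxidant_init": 0.001,
  "water_conc": 55.5,
  "k_for": 1000.0,
  "uracil_hydration_factor": 20.0,
  "K": {
    "1rb5f6aC": 0.0045,
    "5f6aU": 0.09,
    "5fU": 0.000294,
    "5fC": 2.64e-05,
    "5fC_lod": 4.05e-05,
    "5fC_loq": 1.22e-05
  },
  "k_5fU_average": 0.46,
  "k_5dhmU_indirect": 26.2,
  "k_5dhmU_direct": 29.2,
  "k_5dhmU_average": 27.7,
  "k_5dhmC": 364.2
}
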