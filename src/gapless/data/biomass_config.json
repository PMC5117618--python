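{
  "copied_coefficients": {
    "C00001": -59.276,
    "C00002": -59.276,
    "C00008": 59.276,
    "C00009": 59.305,
    "C00059": -0.02,
    "C00255": -0.001
  },
  "trace_compounds": {
    "C00003": "NAD",
    "C00010": "Coenzyme A",
    "C00016": "FAD",
    "C00051": "Glutathione",
    "C00096": "GDP-mannose",
    "C00101": "Tetrahydrofolate",
    "C00575": "3',5'-cyclic AMP",
    "C01083": "alpha,alpha-Trehalose"
  },
  "trace_amount": 1e-06,
  "ester_pool_mmol": 0.0995,
  "mean_ester_mw": 274.2
}
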