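{
  "_note": "Actin chain A of PDB 1D4X with its three CATH-style domains, analyzed both as components of the whole chain and as individual units. Fill 'chains' of 'Partner chains' with the non-actin chain IDs present in the file to enable the P-P / no P-P split.",
  "scale": "kyte_doolittle",
  "cutoff": 9.0,
  "sigma_rule": "std",
  "k_grid": [0.0, 10.0, 0.01],
  "interface_threshold": 9.0,
  "units": [
    {"label": "1D4X Chain A", "chains": ["A"], "mode": "individual"},
    {"label": "Partner chains", "chains": ["B"], "mode": "individual"},
    {"label": "Domain 1 (component)", "ranges": [["A", 4, 137], ["A", 339, 373]], "mode": "component", "parent": "1D4X Chain A", "partners": "Partner chains"},
    {"label": "Domain 2 (component)", "ranges": [["A", 138, 179], ["A", 272, 338]], "mode": "component", "parent": "1D4X Chain A", "partners": "Partner chains"},
    {"label": "Domain 3 (component)", "ranges": [["A", 180, 271]], "mode": "component", "parent": "1D4X Chain A"},
    {"label": "Domain 1 (individual)", "ranges": [["A", 4, 137], ["A", 339, 373]], "mode": "individual", "partners": "Partner chains"},
    {"label": "Domain 2 (individual)", "ranges": [["A", 138, 179], ["A", 272, 338]], "mode": "individual", "partners": "Partner chains"},
    {"label": "Domain 3 (individual)", "ranges": [["A", 180, 271]], "mode": "individual"}
  ]
}
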