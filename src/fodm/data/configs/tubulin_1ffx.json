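{
  "_note": "Tubulin alpha-1 chain A of PDB 1FFX (stathmin-like complex; chains A,C tubulin alpha, B,D tubulin beta, E stathmin helix). Domains analyzed as chain components and as individual units; partners enable the P-P / no P-P split against the rest of the complex.",
  "scale": "kyte_doolittle",
  "cutoff": 9.0,
  "sigma_rule": "std",
  "k_grid": [0.0, 10.0, 0.01],
  "interface_threshold": 9.0,
  "units": [
    {"label": "1FFX Chain A", "chains": ["A"], "mode": "individual", "partners": "Other chains"},
    {"label": "Other chains", "chains": ["B", "C", "D", "E"], "mode": "individual"},
    {"label": "Dom1 (component)", "ranges": [["A", 1, 268]], "mode": "component", "parent": "1FFX Chain A", "partners": "Other chains"},
    {"label": "Dom2 (component)", "ranges": [["A", 269, 383]], "mode": "component", "parent": "1FFX Chain A"},
    {"label": "Dom3 (component)", "ranges": [["A", 384, 440]], "mode": "component", "parent": "1FFX Chain A", "partners": "Other chains"},
    {"label": "Dom1 (individual)", "ranges": [["A", 1, 268]], "mode": "individual", "partners": "Other chains"},
    {"label": "Dom2 (individual)", "ranges": [["A", 269, 383]], "mode": "individual"},
    {"label": "Dom3 (individual)", "ranges": [["A", 384, 440]], "mode": "individual", "partners": "Other chains"}
  ]
}
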