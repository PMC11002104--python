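{
  "_note": "Template for the hexameric prefoldin ('jellyfish') complexes deposited with chaperonin TRiC/CCT (PDB 6NR8, 6NR9, 6NRB, 6NRC, 6NRD). Fill 'chains' with the six prefoldin chain IDs of the deposited file (the files also contain the chaperonin), and supply the beta-sheet 'stem' and helical 'tentacle' residue ranges from the deposited secondary structure; they are not fixed here because they differ per accession.",
  "scale": "kyte_doolittle",
  "cutoff": 9.0,
  "sigma_rule": "std",
  "k_grid": [0.0, 10.0, 0.01],
  "units": [
    {"label": "PFD complex", "chains": ["1", "2", "3", "4", "5", "6"], "mode": "individual"},
    {"label": "Chain 1 (in complex)", "chains": ["1"], "mode": "component", "parent": "PFD complex"},
    {"label": "Chain 1 (individual)", "chains": ["1"], "mode": "individual"},
    {"label": "Helices", "ranges": [["1", 1, 1]], "mode": "component", "parent": "PFD complex"},
    {"label": "Beta-sheets", "ranges": [["1", 1, 1]], "mode": "component", "parent": "PFD complex"},
    {"label": "No helices", "ranges": [["1", 1, 1]], "mode": "component", "parent": "PFD complex"}
  ]
}
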