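{
  "_comment": "Synthetic placeholder calibration: predicted probability that a screened ligand binds at <=10 uM, binned by pocket-similarity p-value (columns; upper edges, most significant first) and identical aligned residues (rows: <4, 4-7, >=8). Values are a documented monotone surface spanning the plausible 0-0.6 range, NOT a benchmarked calibration; supply your own table for production screening.",
  "pvalue_bin_edges": [1e-4, 1e-3, 1e-2, 0.05],
  "n_identical_bin_edges": [4, 8],
  "precision": [
    [0.15, 0.10, 0.05, 0.02],
    [0.35, 0.30, 0.20, 0.10],
    [0.60, 0.55, 0.45, 0.30]
  ]
}
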