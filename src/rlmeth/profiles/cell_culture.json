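{
  "label": "cell_culture",
  "motif_meth_prob": {
    "GANTC": 0.55,
    "GGCGCC": 0.98,
    "GATC": 0.25
  },
  "background_prob": {"A": 0.4, "C": 0.38},
  "replicon_copy_ratio": {
    "Chromosome": 1.0,
    "pRL10": 0.58,
    "pRL11": 0.5,
    "pRL12": 0.48,
    "pSym": 0.6
  },
  "mean_depth": 50.0
}
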