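{
  "label": "bacteroid",
  "motif_meth_prob": {
    "GANTC": 0.98,
    "GGCGCC": 0.98,
    "GATC": {"Chromosome": 0.5, "default": 0.4}
  },
  "background_prob": {"A": 0.75, "C": 0.46},
  "replicon_copy_ratio": {
    "Chromosome": 1.0,
    "pRL10": 0.91,
    "pRL11": 0.94,
    "pRL12": 0.97,
    "pSym": 0.59
  },
  "mean_depth": 50.0
}
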