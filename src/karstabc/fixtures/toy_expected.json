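{
  "alignment": {
    "n": 6, "length": 10, "k": 5,
    "hap_counts": [2, 1, 1, 1, 1],
    "h": 0.9333333333333331, "h_sd": 0.12171612389003686,
    "pi": 0.3066666666666667, "pi_sd": 0.21368027344436658,
    "S": 6, "W": 3.066666666666667
  },
  "genotypes": {
    "Ho_locusA": 0.6, "He_locusA": 0.6444444444444444,
    "AR2_locusA": 1.6444444444444446,
    "Ho_locusB": 0.0, "He_locusB": 0.0, "AR2_locusB": 1.0,
    "Fis": 0.07692307692307687,
    "Ho_mean": 0.3, "He_mean": 0.3222222222222222, "AR_mean": 1.3222222222222224
  },
  "allele_tables": {
    "fixed_2x2": {"table": [[3, 0], [0, 3]], "p": 0.1},
    "mixed_2x3": {"table": [[2, 1, 0], [0, 1, 2]], "p": 0.6}
  },
  "hwe": {
    "aa_bb": {"genotypes": [[1, 1], [2, 2]], "p": 0.3333333333333333},
    "ab_ab": {"genotypes": [[1, 2], [1, 2]], "p": 1.0}
  },
  "rejection": {
    "observed": [0.0, 0.0],
    "norm": [1.0, 2.0],
    "distances": [1.4142135623730951, 2.0, 5.0]
  }
}
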