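{
  "seed": 1,
  "cutoff_gy": 200.0,
  "cv_folds": 10,
  "n_trees": 500,
  "boruta_max_runs": 500,
  "exclusion_threshold": 2
}
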