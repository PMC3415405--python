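# Published analysis settings: detection and merge thresholds at 1%,
# DE threshold at 5%, expression call across >= 4 arrays per group,
# positional run lengths 2 and 3.
detection_alpha: 0.01
min_arrays: 4
merge_alpha: 0.01
de_alpha: 0.05
collapse_rule: max-mean
equality_mode: pvalue
equality_band: [0.95, 1.05]
k_values: [2, 3]
n_sims: 100000
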