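{
 "if_mean_signed": 0.388681,
 "if_mean_abs": 0.388681,
 "if_n_positive": 5,
 "if_cluster_p": 0.0625,
 "peak_auc": 0.833333,
 "burst_rates": {
  "A": 2.691667,
  "B": 2.775
 }
}
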