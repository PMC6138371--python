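{
 "table1_concordance.csv": "94c3d8373959fb80a67ca90a77a0693857aec9b675f1127aec51d523648cdd94",
 "table2_clusters_hcn.csv": "fae33948f17eada17397d0cb7475448e88e97dea2ce97d6e4f4967c83f71244d",
 "table3_clusters_cn.csv": "4787856c51cf298564fd23af6369087625fb0ab2e2e7f4f1e5326a3623ae4180"
}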