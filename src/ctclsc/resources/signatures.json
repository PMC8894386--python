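{
  "cytotoxicity": ["GZMA", "GZMB", "GZMK", "IFNG", "NKG7", "PRF1", "CST7", "CCL4"],
  "exhaustion": ["PDCD1", "LAG3", "TIGIT", "HAVCR2", "CTLA4"],
  "central_memory": ["CCR7", "SELL", "CD27", "TCF7", "LEF1"]
}
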