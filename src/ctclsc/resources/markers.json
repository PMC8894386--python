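{
  "T cells": ["PTPRC", "CD3E", "CD3D", "CD3G"],
  "B cells": ["CD19", "CD79A", "MS4A1", "CD79B"],
  "Macrophages": ["LYZ", "CD14", "CD68", "C1QA"],
  "Myofibroblasts": ["ACTA2", "TAGLN", "MYLK", "AOC3"],
  "Endothelial cells": ["PLVAP", "CLDN5", "ENG", "AQP1"],
  "Plasma cells": ["IGLL5", "MZB1", "DERL3", "FKBP11"],
  "Fibroblasts": ["DCN", "COL1A1", "COL3A1", "COL1A2"],
  "ILC1s/NKs": ["GNLY", "KLRB1", "IL7R", "GZMB", "NKG7", "PRF1", "FCGR3A", "KLRD1"],
  "Epithelial cells": ["KRT14", "KRT5", "KRT6A", "KRT17"],
  "pDCs": ["IRF7", "LILRA4", "PLD4", "PLAC8"],
  "DCs": ["FSCN1", "LAMP3", "CD1E", "CCR7"],
  "Mast cells": ["CPA3", "HPGD", "CTSG", "GATA2"],
  "Melanocytes": ["PMEL", "TYRP1", "DCT", "MLANA"]
}
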