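{
  "A": "nutlin-3 treated neuroblastoma cells",
  "B": "ATRA treated neuroblastoma cells",
  "C": "withaferin A treated neuroblastoma cells",
  "D": "TAE-684 treated neuroblastoma cells",
  "E": "neuroblastoma cells transfected with siRNAs against T-UCRs",
  "F": "neuroblastoma cells transfected with miR-1 mimic",
  "G": "T-ALL cell lines (HPB-ALL, ALL-SIL, and TALL-1) transfected with miR-223 mimic or negative control miRNA mimic",
  "H": "T-ALL cell line JURKAT transfected with PHF6-targeting siRNA or negative control siRNA",
  "I": "T-ALL cell lines (HSB-2 and PF-382) transfected with PHF6-targeting siRNA or negative control siRNA",
  "J": "NSCL cell line (H3122) treated with crizotinib",
  "K": "melanoma cell line (WM-9) transfected with siRNA against cyclophilin-B",
  "L": "AML cell line (K562) treated with JQ1",
  "M": "breast cancer cell line (MCF-7) treated with JQ1",
  "N": "breast cancer cell line (SKBR-3) treated with JQ1",
  "O": "prostate cancer cell line (PC-3) treated with JQ1",
  "P": "colorectal cancer cell line (SW-620) treated with JQ1",
  "Q": "neuroblastoma cell line (SJNB-12) treated with JQ1",
  "R": "MCF-7 cells treated with 90 different chemical inhibitors",
  "S": "cervical cancer cell line (HeLa) treated with 90 different chemical inhibitors"
}
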