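{
  "gene": "NUD (barley chromosome 7H; loss of function gives naked caryopses)",
  "guide_name": "sgRNA8",
  "protospacer": "GGCTGCGCGGGCGTACGATG",
  "pam_pattern": "NGG",
  "target_site_with_pam": "GGCTGCGCGGGCGTACGATGNGG",
  "amplicon_context": "CGGCGGAGGAGGCTGCGCGGGCGTACGATGAGGCTGCCATCCT",
  "context_note": "43-nt genomic context around the sgRNA8 target site; protospacer at positions 11-30, PAM (AGG) at 31-33"
}
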