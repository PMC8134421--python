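{
  "categorical": [
    "Chrom", "Ref", "Alt", "Type", "AnnoType", "Consequence", "ConsDetail",
    "motifEName", "oAA", "nAA", "GeneID", "FeatureID", "GeneName",
    "Domain", "Dst2SplType", "SIFTcat", "PolyPhenCat", "Segway"
  ],
  "binary": [
    "motifEHIPos", "CCDS", "Intron", "Exon"
  ]
}
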