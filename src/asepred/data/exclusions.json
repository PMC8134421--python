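{
  "non_functional": [
    "Chrom", "Pos", "Length", "ConsScore", "ConsDetail", "motifEName",
    "FeatureID", "GeneID", "GeneName", "CCDS", "Intron", "Exon"
  ],
  "high_missingness": [
    "motifECount", "motifEHIPos", "motifEScoreChng", "Dst2Splice",
    "Dst2SplType", "targetScan", "mirSVR-Score", "mirSVR-E", "mirSVR-Aln",
    "TFBS", "TFBSPeaks", "TFBSPeaksMax", "tOverlapMotifs", "motifDist",
    "dbscSNV-ada_score", "dbscSNV-rf_score"
  ],
  "detectability_correlated": [
    "EncExp", "gnomAD_AF", "Freq100bp", "Rare100bp", "Sngl100bp",
    "Freq1000bp", "Rare1000bp", "Sngl1000bp", "Freq10000bp", "Rare10000bp",
    "Sngl10000bp"
  ]
}
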