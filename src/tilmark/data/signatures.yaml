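# Immune gene-expression signatures used for GEP scoring.
#
# The three published anti-PD-1 response signatures (IFN-gamma, Expanded
# immune, T-cell inflamed GEP).  These lists are data, not code: edit or
# extend this file (or pass --signatures) to score custom gene sets.
IFN-gamma:
  - IDO1
  - CXCL10
  - CXCL9
  - HLA-DRA
  - STAT1
  - IFNG
ExpandedImmune:
  - CD3D
  - IDO1
  - CIITA
  - CD3E
  - CCL5
  - GZMK
  - CD2
  - HLA-DRA
  - CXCL13
  - IL2RG
  - NKG7
  - HLA-E
  - CXCR6
  - LAG3
  - TAGAP
  - CXCL10
  - STAT1
  - GZMB
TcellInflamed:
  - CCL5
  - CD27
  - CD274
  - CD276
  - CD8A
  - CMKLR1
  - CXCL9
  - CXCR6
  - HLA-DQA1
  - HLA-DRB1
  - HLA-E
  - IDO1
  - LAG3
  - NKG7
  - PDCD1LG2
  - PSMB10
  - STAT1
  - TIGIT
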