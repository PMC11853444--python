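# Adverse risk-defining somatic mutations per the ELN, Pethema Registry and
# NCRI classifications for myeloid malignancies.  FLT3-ITD is a distinct
# marker; FLT3 point mutations are not adverse under this list.
source_label: "ELN / Pethema / NCRI adverse-risk gene list"
adverse:
  - ASXL1
  - BCOR
  - EZH2
  - FLT3-ITD
  - RUNX1
  - SETBP1
  - SF3B1
  - SRSF2
  - STAG2
  - TP53
  - U2AF1
  - ZRSR2
  - WT1
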