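# Genes involved in DNA and histone (de)methylation screened for
# enrichment in methylation groups. One symbol per line; '#' comments.
DNMT1
DNMT3A
DNMT3B
TET1
TET2
TET3
IDH1
IDH2
KMT2A
KMT2B
KMT2C
KMT2D
SETD1A
SETD1B
SETD2
NSD1
NSD2
NSD3
KDM1A
KDM2A
KDM2B
KDM4A
KDM5A
KDM5B
KDM5C
KDM6A
KDM6B
PRDM1
PRDM2
PRDM9
EHMT1
EHMT2
SMYD2
SMYD3
MBD1
MBD2
MBD3
MBD4
MECP2
CTCF
CTCFL
UHRF1
UHRF2
BAZ2A
ATRX
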