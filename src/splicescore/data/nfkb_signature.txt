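# Default NF-kB response gene signature (editable placeholder).
# Built in the spirit of intersecting curated NF-kB target collections
# with experimentally observed human response genes; substitute your
# own curated list (one HGNC symbol per line) for real-data use.
TNF
IL6
IL1B
NFKBIA
NFKBIE
NFKB1
NFKB2
RELB
TNFAIP3
TNFAIP6
CXCL8
CXCL1
CXCL2
CCL2
CCL20
ICAM1
VCAM1
SOD2
BIRC3
TRAF1
CD83
IER3
PLAU
PTGS2
SELE
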