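# Default interferon-stimulated gene signature (editable placeholder).
# The IFN score in the analysis is an aggregate of control-referenced
# Z scores over a curated ISG list; substitute your own curated list
# (one HGNC symbol per line) for real-data use.  These are canonical
# type I IFN response genes widely used in blood IFN signatures.
IFI27
IFI44
IFI44L
IFI6
IFIT1
IFIT3
ISG15
LY6E
MX1
MX2
OAS1
OAS2
OAS3
OASL
RSAD2
SIGLEC1
USP18
HERC5
IFIH1
STAT1
STAT2
IRF7
EPSTI1
CMPK2
XAF1
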