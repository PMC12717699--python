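# Default housekeeping gene panel used by the housekeeping-expression QC filter.
# Constitutively expressed genes spanning cytoskeleton, glycolysis, ribosome,
# translation and ubiquitin pathways. Override with any one-symbol-per-line file.
ACTB
GAPDH
B2M
TUBB
PPIA
RPL13A
RPLP0
RPS18
HPRT1
TBP
UBC
YWHAZ
PGK1
GUSB
SDHA
TFRC
EEF1A1
RPL7
RPS27A
PSMB4
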