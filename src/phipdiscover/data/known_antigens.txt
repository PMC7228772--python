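# Curated literature-reported APS1/APECED autoantigens (gene symbols).
# One symbol per line; lines starting with '#' are ignored.
CYP11A1
CYP17A1
CYP21A1
CYP1A2
KCNRG
IL17A
IL17F
IL22
SOX10
NLRP5
TPH1
DDC
BPIFB1
GAD2
INS
LCN1
MAGEB2
PDILT
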