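# Interferon-regulated gene list (synthetic stand-in assembled from the
# packaged differential-expression table's IFN-regulated flags plus the
# six-gene IFN-score panel; one gene symbol per line).
S100A8
VCAN
S100A9
CD163
SERPINA1
ANXA1
PLAUR
CPVL
HK3
FCN1
CD36
CST3
PYGL
USP18
HDX
RSAD2
SLC30A1
PLOD1
CCNG1
SKAP2
DNAJB6
DNAJA1
HEXB
SNX6
YME1L1
SLC2A11
MAGED1
UNKL
PPP1R3E
TMEM198B
L3MBTL1
NSUN5P2
IFI27
IFI44L
IFIT1
ISG15
SIGLEC1
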