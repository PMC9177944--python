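IFI27
IFI44L
IFIT1
ISG15
RSAD2
SIGLEC1
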