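ethanol
acetone
pentane
isoprene
carbon disulphide
pentanal
2-pentanone
hexanal
2-octanone
alpha-pinene
benzaldehyde
decane
limonene
undecane
dodecane
decanal
octane
nonane
tridecane
undecanal
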