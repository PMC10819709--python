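sulfur dioxide
methyl formate
formic acid methyl ester
ethanol
trimethylamine
acrolein
acetone
2-propanol
isoprene
pentane
dimethyl sulfide
metylacetate
carbon disulfide
1-propanol
acetic acid
butanal
2-butanone
hexane
2-butanol
dimethyl carbonate
isobutyl alcohol
methyl propionate
1-butanol
benzene
2-pentanone
propanoic acid
cyclopentanol
pentanal
acetic acid propyl ester
butanoic acid methyl ester
isobutyric acid
dimethyl disulfide
pyrrole
toluene
butanoic acid
2-hexanone
butyric acid ethyl ester
hexanal
octane
propionic acid propyl ester
acetic acid butyl ester
isovaleric acid
2-methyl butyric acid
n,n-dimethyl acetamide
pentanoic acid
nonane
styrene
dimethylsulfone
hexanoic acid methyl ester
hexanoic acid
benzaldehyde
phenol
dimethyltrisulfide
octanal
3-carene
limonene
p-cresol
nonanal
decanal
methane amine
indole
6-methyl indole
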