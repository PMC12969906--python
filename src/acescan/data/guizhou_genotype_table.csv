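# 12-population Anopheles sinensis survey, Guizhou Province: printed
# genotype frequencies (%) at ace-1 codon 119 and the sample size n.
# Counts are reconstructed as round(n * pct / 100); the ZJ population
# carried the only GGT-bearing individual (one GGT/GGT homozygote, 2
# alleles).
population,n,pct_GG,pct_SS,pct_GS,n_GGT_alleles
LP,50,88,0,12,0
CH,50,0,34,66,0
LD,25,0,40,60,0
SD,49,0,22,78,0
XR,51,8,43,49,0
PB,50,24,14,62,0
ZJ,50,16,26,58,2
HX,50,22,18,60,0
DY,50,34,4,62,0
XS,26,4,12,85,0
TZ,50,4,4,92,0
DJ,50,4,18,78,0
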