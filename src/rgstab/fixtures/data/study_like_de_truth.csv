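gene,log2fc,fdr,mean_count
ADF2,0.000000,1.000000,800
CYB5,0.000000,1.000000,1200
iPGAM,0.000000,1.000000,300
SCL13,0.000000,1.000000,250
TRXL3-3,0.000000,1.000000,500
VHA-H,0.000000,1.000000,650
ACT,2.000000,0.000000,5000
GAPDH-2C,-1.800000,0.000000,4000
UPL6,2.500000,0.000000,150
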