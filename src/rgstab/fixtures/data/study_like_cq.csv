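sample_id,group,gene,replicate,cq,efficiency
C_1,C,ADF2,1,32.152126,1.950000
C_1,C,ADF2,2,32.212771,1.950000
C_2,C,ADF2,1,31.097015,1.950000
C_2,C,ADF2,2,31.004049,1.950000
C_3,C,ADF2,1,31.538289,1.950000
C_3,C,ADF2,2,31.368110,1.950000
DI-1_1,DI-1,ADF2,1,31.732550,1.950000
DI-1_1,DI-1,ADF2,2,31.635694,1.950000
DI-1_2,DI-1,ADF2,1,31.408232,1.950000
DI-1_2,DI-1,ADF2,2,31.421787,1.950000
DI-1_3,DI-1,ADF2,1,31.736720,1.950000
DI-1_3,DI-1,ADF2,2,31.512029,1.950000
DI-2_1,DI-2,ADF2,1,30.692683,1.950000
DI-2_1,DI-2,ADF2,2,30.729852,1.950000
DI-2_2,DI-2,ADF2,1,31.145948,1.950000
DI-2_2,DI-2,ADF2,2,31.008654,1.950000
DI-2_3,DI-2,ADF2,1,31.150231,1.950000
DI-2_3,DI-2,ADF2,2,31.079280,1.950000
C_1,C,CYB5,1,32.201148,1.880000
C_1,C,CYB5,2,31.884348,1.880000
C_2,C,CYB5,1,31.761569,1.880000
C_2,C,CYB5,2,32.010110,1.880000
C_3,C,CYB5,1,32.140648,1.880000
C_3,C,CYB5,2,32.229518,1.880000
DI-1_1,DI-1,CYB5,1,31.662347,1.880000
DI-1_1,DI-1,CYB5,2,31.540597,1.880000
DI-1_2,DI-1,CYB5,1,32.187050,1.880000
DI-1_2,DI-1,CYB5,2,32.210959,1.880000
DI-1_3,DI-1,CYB5,1,31.820674,1.880000
DI-1_3,DI-1,CYB5,2,31.722113,1.880000
DI-2_1,DI-2,CYB5,1,31.157937,1.880000
DI-2_1,DI-2,CYB5,2,31.386936,1.880000
DI-2_2,DI-2,CYB5,1,31.775558,1.880000
DI-2_2,DI-2,CYB5,2,31.572887,1.880000
DI-2_3,DI-2,CYB5,1,31.862932,1.880000
DI-2_3,DI-2,CYB5,2,31.682697,1.880000
C_1,C,iPGAM,1,37.164255,1.920000
C_1,C,iPGAM,2,37.226496,1.920000
C_2,C,iPGAM,1,37.447775,1.920000
C_2,C,iPGAM,2,37.627318,1.920000
C_3,C,iPGAM,1,37.088515,1.920000
C_3,C,iPGAM,2,37.185412,1.920000
DI-1_1,DI-1,iPGAM,1,37.309447,1.920000
DI-1_1,DI-1,iPGAM,2,37.395230,1.920000
DI-1_2,DI-1,iPGAM,1,37.524008,1.920000
DI-1_2,DI-1,iPGAM,2,37.575123,1.920000
DI-1_3,DI-1,iPGAM,1,37.512700,1.920000
DI-1_3,DI-1,iPGAM,2,37.366405,1.920000
DI-2_1,DI-2,iPGAM,1,37.248527,1.920000
DI-2_1,DI-2,iPGAM,2,37.218101,1.920000
DI-2_2,DI-2,iPGAM,1,37.406855,1.920000
DI-2_2,DI-2,iPGAM,2,37.370043,1.920000
DI-2_3,DI-2,iPGAM,1,37.760621,1.920000
DI-2_3,DI-2,iPGAM,2,37.849590,1.920000
C_1,C,SCL13,1,36.874060,1.800000
C_1,C,SCL13,2,36.738264,1.800000
C_2,C,SCL13,1,36.852710,1.800000
C_2,C,SCL13,2,36.936962,1.800000
C_3,C,SCL13,1,36.970911,1.800000
C_3,C,SCL13,2,36.916222,1.800000
DI-1_1,DI-1,SCL13,1,36.965407,1.800000
DI-1_1,DI-1,SCL13,2,37.064295,1.800000
DI-1_2,DI-1,SCL13,1,36.615614,1.800000
DI-1_2,DI-1,SCL13,2,36.377147,1.800000
DI-1_3,DI-1,SCL13,1,36.738953,1.800000
DI-1_3,DI-1,SCL13,2,36.662614,1.800000
DI-2_1,DI-2,SCL13,1,36.613384,1.800000
DI-2_1,DI-2,SCL13,2,36.632954,1.800000
DI-2_2,DI-2,SCL13,1,36.094404,1.800000
DI-2_2,DI-2,SCL13,2,36.182738,1.800000
DI-2_3,DI-2,SCL13,1,36.840951,1.800000
DI-2_3,DI-2,SCL13,2,36.808573,1.800000
C_1,C,TRXL3-3,1,34.129245,1.900000
C_1,C,TRXL3-3,2,34.254381,1.900000
C_2,C,TRXL3-3,1,34.024770,1.900000
C_2,C,TRXL3-3,2,33.832568,1.900000
C_3,C,TRXL3-3,1,34.409552,1.900000
C_3,C,TRXL3-3,2,34.387638,1.900000
DI-1_1,DI-1,TRXL3-3,1,34.277628,1.900000
DI-1_1,DI-1,TRXL3-3,2,34.406021,1.900000
DI-1_2,DI-1,TRXL3-3,1,34.575056,1.900000
DI-1_2,DI-1,TRXL3-3,2,34.397412,1.900000
DI-1_3,DI-1,TRXL3-3,1,34.169303,1.900000
DI-1_3,DI-1,TRXL3-3,2,34.031336,1.900000
DI-2_1,DI-2,TRXL3-3,1,33.670282,1.900000
DI-2_1,DI-2,TRXL3-3,2,33.821725,1.900000
DI-2_2,DI-2,TRXL3-3,1,34.998070,1.900000
DI-2_2,DI-2,TRXL3-3,2,34.787313,1.900000
DI-2_3,DI-2,TRXL3-3,1,34.322180,1.900000
DI-2_3,DI-2,TRXL3-3,2,34.299341,1.900000
C_1,C,VHA-H,1,32.940519,1.970000
C_1,C,VHA-H,2,32.894692,1.970000
C_2,C,VHA-H,1,32.921994,1.970000
C_2,C,VHA-H,2,32.787121,1.970000
C_3,C,VHA-H,1,33.311653,1.970000
C_3,C,VHA-H,2,33.608253,1.970000
DI-1_1,DI-1,VHA-H,1,33.934357,1.970000
DI-1_1,DI-1,VHA-H,2,33.839729,1.970000
DI-1_2,DI-1,VHA-H,1,34.103327,1.970000
DI-1_2,DI-1,VHA-H,2,34.161365,1.970000
DI-1_3,DI-1,VHA-H,1,34.433046,1.970000
DI-1_3,DI-1,VHA-H,2,34.240484,1.970000
DI-2_1,DI-2,VHA-H,1,35.493611,1.970000
DI-2_1,DI-2,VHA-H,2,35.386499,1.970000
DI-2_2,DI-2,VHA-H,1,35.456417,1.970000
DI-2_2,DI-2,VHA-H,2,35.445163,1.970000
DI-2_3,DI-2,VHA-H,1,35.613801,1.970000
DI-2_3,DI-2,VHA-H,2,35.473209,1.970000
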