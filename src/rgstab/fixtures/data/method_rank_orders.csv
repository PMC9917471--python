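experiment,method,rank,gene
green_vs_red,geNorm,1,CYB5
green_vs_red,geNorm,2,ADF2
green_vs_red,geNorm,3,TRXL3-3
green_vs_red,geNorm,4,VHA-H
green_vs_red,geNorm,5,iPGAM
green_vs_red,geNorm,6,SCL13
green_vs_red,NormFinder,1,TRXL3-3
green_vs_red,NormFinder,2,VHA-H
green_vs_red,NormFinder,3,CYB5
green_vs_red,NormFinder,4,ADF2
green_vs_red,NormFinder,5,iPGAM
green_vs_red,NormFinder,6,SCL13
green_vs_red,BestKeeper,1,TRXL3-3
green_vs_red,BestKeeper,2,CYB5
green_vs_red,BestKeeper,3,SCL13
green_vs_red,BestKeeper,4,ADF2
green_vs_red,BestKeeper,5,iPGAM
green_vs_red,BestKeeper,6,VHA-H
green_vs_red,DeltaCt,1,CYB5
green_vs_red,DeltaCt,2,ADF2
green_vs_red,DeltaCt,3,SCL13
green_vs_red,DeltaCt,4,TRXL3-3
green_vs_red,DeltaCt,5,iPGAM
green_vs_red,DeltaCt,6,VHA-H
leaf_vs_stem,geNorm,1,CYB5
leaf_vs_stem,geNorm,2,ADF2
leaf_vs_stem,geNorm,3,TRXL3-3
leaf_vs_stem,geNorm,4,VHA-H
leaf_vs_stem,geNorm,5,iPGAM
leaf_vs_stem,geNorm,6,SCL13
leaf_vs_stem,NormFinder,1,TRXL3-3
leaf_vs_stem,NormFinder,2,VHA-H
leaf_vs_stem,NormFinder,3,ADF2
leaf_vs_stem,NormFinder,4,CYB5
leaf_vs_stem,NormFinder,5,iPGAM
leaf_vs_stem,NormFinder,6,SCL13
leaf_vs_stem,BestKeeper,1,TRXL3-3
leaf_vs_stem,BestKeeper,2,iPGAM
leaf_vs_stem,BestKeeper,3,CYB5
leaf_vs_stem,BestKeeper,4,ADF2
leaf_vs_stem,BestKeeper,5,SCL13
leaf_vs_stem,BestKeeper,6,VHA-H
leaf_vs_stem,DeltaCt,1,TRXL3-3
leaf_vs_stem,DeltaCt,2,CYB5
leaf_vs_stem,DeltaCt,3,iPGAM
leaf_vs_stem,DeltaCt,4,ADF2
leaf_vs_stem,DeltaCt,5,VHA-H
leaf_vs_stem,DeltaCt,6,SCL13
drought,geNorm,1,TRXL3-3
drought,geNorm,2,ADF2
drought,geNorm,3,CYB5
drought,geNorm,4,iPGAM
drought,geNorm,5,SCL13
drought,geNorm,6,VHA-H
drought,NormFinder,1,TRXL3-3
drought,NormFinder,2,ADF2
drought,NormFinder,3,iPGAM
drought,NormFinder,4,CYB5
drought,NormFinder,5,SCL13
drought,NormFinder,6,VHA-H
drought,BestKeeper,1,TRXL3-3
drought,BestKeeper,2,SCL13
drought,BestKeeper,3,iPGAM
drought,BestKeeper,4,ADF2
drought,BestKeeper,5,CYB5
drought,BestKeeper,6,VHA-H
drought,DeltaCt,1,SCL13
drought,DeltaCt,2,TRXL3-3
drought,DeltaCt,3,iPGAM
drought,DeltaCt,4,ADF2
drought,DeltaCt,5,CYB5
drought,DeltaCt,6,VHA-H
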