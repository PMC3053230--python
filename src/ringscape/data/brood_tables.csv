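table,transgene_id,genotype,mean,sem,n
1,xyEx186,C681A,39,6,10
1,xyEx187,C681A,51,11,7
1,xyEx188,C681A,63,12,5
1,xyEx69,C684A,6,2,9
1,xyEx72,C684A,<1,,6
1,xyEx77,C684A,0,0,9
1,xyEx48,C700A,<1,,8
1,xyEx52,C700A,1,0.68,8
1,xyEx63,C700A,<1,,10
1,xyEx134,C703A,3,1,12
1,xyEx135,C703A,<1,,9
1,xyEx136,C703A,3,1,10
1,xyEx73,C708A,0,0,5
1,xyEx78,C708A,0,0,5
1,xyEx80,C708A,0,0,5
1,xyEx74,C711A,<1,,9
1,xyEx81,C711A,3,1,10
1,xyEx129,C711A,2,0.76,6
1,xyEx130,C718A,0,0,9
1,xyEx131,C718A,<1,,9
1,xyEx132,C718A,0,0,9
1,xyEx85,C721A,2,0.60,9
1,xyEx86,C721A,5,2,10
1,xyEx87,C721A,11,1,9
1,ebEx498,wild type,92,16,11
1,xyEx175,wild type,123,15,10
1,xyEx177,wild type,115,17,11
1,N2,N2,185,5,10
1,spe-42(tn1231),spe-42 null,0,0,24
1,spe-42(tm2421),spe-42 null,0,0,15
2,xyEx208,C678A,117,22,10
2,xyEx209,C678A,101,22,9
2,xyEx212,C678A,113,13,8
2,xyEx186,C681A,39,6,10
2,xyEx187,C681A,51,11,7
2,xyEx188,C681A,63,12,5
2,xyEx207,C678A; C681A,3,1,10
2,xyEx213,C678A; C681A,2,1,10
2,xyEx220,C678A; C681A,1,0.65,10
2,ebEx498,wild type,92,16,11
2,xyEx175,wild type,123,15,10
2,xyEx177,wild type,115,17,11
2,N2,N2,185,5,10
2,spe-42(tn1231),spe-42 null,0,0,24
2,spe-42(tm2421),spe-42 null,0,0,15
3,ebEx498,wild type,92,16,11
3,xyEx175,wild type,123,15,10
3,xyEx177,wild type,115,17,11
3,xyEx1,C. briggsae,2,1,10
3,xyEx2,C. briggsae,1,0.62,9
3,xyEx3,C. briggsae,6,2,9
3,xyEx27,C. briggsae + C. elegans exon,11,4,10
3,xyEx30,C. briggsae + C. elegans exon,8,4,10
3,xyEx34,C. briggsae + C. elegans exon,17,4,10
3,xyEx36,C. elegans + C. briggsae exon,83,15,9
3,xyEx37,C. elegans + C. briggsae exon,110,10,8
3,xyEx41,C. elegans + C. briggsae exon,123,15,10
3,N2,N2,185,5,10
3,spe-42(tn1231),spe-42 null,0,0,24
3,spe-42(tm2421),spe-42 null,0,0,15
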