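dataset,lesion_type,count
discovery,MEL,510
discovery,NV,1170
discovery,BCC,1481
discovery,AKIEC,2122
discovery,BKL,897
discovery,DF,88
discovery,VASC,102
discovery,OB,826
isic2018,MEL,1113
isic2018,NV,6705
isic2018,BCC,514
isic2018,AKIEC,327
isic2018,BKL,1099
isic2018,DF,115
isic2018,VASC,142
test,MEL,50
test,NV,139
test,BCC,76
test,AKIEC,121
test,BKL,83
test,DF,11
test,VASC,5
test,OB,17
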