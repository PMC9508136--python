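dataset,quantity,mean_area_px2
discovery,lesion,307699
discovery,image,8036107
test,lesion,458619
test,image,7755934
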