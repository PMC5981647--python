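component,pred_mix_30_70,pred_mix_50_50,pred_mix_70_30,true_mix_30_70,true_mix_50_50,true_mix_70_30
2-butanone,33,46,71,30,50,70
1-propanol,75,53,25,70,50,30
isoprene,2,0,-3,0,0,0
ethylbenzene,4,-1,-1,0,0,0
styrene,-6,-2,4,0,0,0
hexanal,-8,4,3,0,0,0
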