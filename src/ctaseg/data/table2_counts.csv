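feature_set,tn,tp,fn,fp,fp_group_b,dsc,sensitivity,specificity,combined_dsc
cta,78,99,6,117,92,0.62,0.94,0.40,0.48
cta+flip,158,98,7,37,46,0.82,0.93,0.81,0.69
cta+flip+ncct,159,98,7,36,34,0.82,0.93,0.82,0.72
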