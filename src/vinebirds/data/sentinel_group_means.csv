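group,n_transects,mean_removed,se
control,10,1.2,1.0
nestbox_random,10,2.9,0.6
active_nest,7,4.14,0.6
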