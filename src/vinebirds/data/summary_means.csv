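response,nestbox_mean,nestbox_se,control_mean,control_se
richness,4.23,0.39,3.67,0.19
insectivore_richness,2.01,0.07,1.21,0.25
total_abundance,3.71,0.43,2.09,0.33
bluebird_abundance,1.82,0.14,0.18,0.05
nonbluebird_insectivore_abundance,0.84,0.11,0.47,0.15
omnivore_abundance,0.14,0.09,0.18,0.02
granivore_abundance,1.20,0.31,1.23,0.11
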