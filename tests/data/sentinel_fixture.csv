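site,block,group,o1,o2,o3,o4,o5
S1,S1-control,control,present,present,removed,removed,present
S1,S1-control,control,removed,present,present,removed,removed
S1,S1-control,control,removed,present,present,removed,present
S1,S1-control,control,present,removed,present,present,present
S1,S1-control,control,present,removed,present,present,removed
S1,S1-nestbox,nestbox_random,removed,removed,present,present,present
S1,S1-nestbox,nestbox_random,present,present,removed,removed,removed
S1,S1-nestbox,nestbox_random,removed,removed,present,removed,removed
S1,S1-nestbox,nestbox_random,removed,removed,present,removed,present
S1,S1-nestbox,nestbox_random,present,removed,present,present,removed
S1,S1-nestbox,active_nest,present,removed,removed,removed,removed
S1,S1-nestbox,active_nest,present,removed,removed,removed,present
S1,S1-nestbox,active_nest,removed,removed,removed,present,removed
S1,S1-nestbox,active_nest,removed,present,removed,present,removed
S2,S2-control,control,present,present,present,present,present
S2,S2-control,control,removed,removed,present,present,present
S2,S2-control,control,present,present,removed,present,present
S2,S2-control,control,present,present,present,present,present
S2,S2-control,control,present,present,present,present,removed
S2,S2-nestbox,nestbox_random,removed,present,removed,removed,removed
S2,S2-nestbox,nestbox_random,present,present,present,present,present
S2,S2-nestbox,nestbox_random,removed,present,removed,removed,removed
S2,S2-nestbox,nestbox_random,removed,present,removed,present,removed
S2,S2-nestbox,nestbox_random,present,present,present,present,removed
S2,S2-nestbox,active_nest,removed,present,removed,removed,removed
S2,S2-nestbox,active_nest,present,removed,removed,removed,removed
S2,S2-nestbox,active_nest,present,removed,removed,removed,removed
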