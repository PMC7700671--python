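,house,tree,road,soil,grass,others
house,697,8,24,35,16,12
tree,1,820,4,6,63,55
road,83,3,846,13,2,1
soil,140,5,7,734,66,4
grass,19,72,4,52,509,5
others,12,55,2,8,5,963
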