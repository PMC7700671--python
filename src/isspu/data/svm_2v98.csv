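,house,tree,road,soil,grass,others
house,0,6,551,176,27,32
tree,0,791,4,5,89,60
road,0,3,910,30,3,2
soil,0,5,18,844,85,4
grass,0,83,20,46,503,9
others,0,75,4,8,9,949
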