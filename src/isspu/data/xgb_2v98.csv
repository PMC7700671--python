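,house,tree,road,soil,grass,others
house,32,8,259,250,207,36
tree,0,813,4,5,62,65
road,0,4,917,21,6,0
soil,1,5,11,857,78,4
grass,0,73,7,51,524,6
others,0,49,3,8,12,973
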