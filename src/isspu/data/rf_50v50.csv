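,house,tree,road,soil,grass,others
house,570,6,143,46,17,10
tree,1,806,4,6,72,60
road,31,2,883,28,4,0
soil,22,4,7,845,74,4
grass,20,75,6,45,511,4
others,13,62,2,7,7,954
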