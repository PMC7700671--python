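,house,tree,road,soil,grass,others
house,0,10,451,283,20,28
tree,0,798,4,6,80,61
road,0,3,907,33,3,2
soil,0,4,9,864,72,7
grass,0,76,16,58,497,14
others,0,70,6,9,9,951
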