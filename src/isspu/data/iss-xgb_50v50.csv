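,house,tree,road,soil,grass,others
house,700,6,20,49,7,10
tree,1,821,4,6,61,56
road,69,3,855,19,2,0
soil,17,5,9,849,72,4
grass,19,70,4,47,516,5
others,12,52,2,8,7,964
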