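,house,tree,road,soil,grass,others
house,697,6,23,47,8,11
tree,1,812,4,7,61,64
road,48,3,876,19,2,0
soil,19,5,10,841,77,4
grass,18,73,5,50,511,4
others,11,50,3,7,8,966
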