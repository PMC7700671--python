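,house,tree,road,soil,grass,others
house,560,11,147,50,14,10
tree,1,807,4,6,73,58
road,28,3,887,28,2,0
soil,18,5,14,840,73,6
grass,18,78,15,45,496,9
others,13,79,2,7,8,936
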