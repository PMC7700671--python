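,house,tree,road,soil,grass,others
house,2,6,226,366,164,28
tree,0,802,3,6,72,66
road,0,3,908,34,2,1
soil,0,3,14,861,73,5
grass,0,74,7,55,520,5
others,0,67,3,11,8,956
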