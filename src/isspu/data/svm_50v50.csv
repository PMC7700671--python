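,house,tree,road,soil,grass,others
house,616,6,91,48,20,11
tree,1,792,4,5,89,58
road,39,3,880,23,3,0
soil,24,6,18,823,82,3
grass,20,86,7,39,502,7
others,12,82,3,7,6,935
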