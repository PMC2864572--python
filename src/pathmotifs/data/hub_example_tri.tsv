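n01	n02
n01	n03
n02	n05
n03	n06
n04	n03
n04	n07
n10	n13
n12	n02
n12	n14
n13	n15
n20	n19
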