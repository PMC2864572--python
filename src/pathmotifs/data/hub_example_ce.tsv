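n01	n05
n01	n06
n01	n08
n01	n14
n01	n15
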