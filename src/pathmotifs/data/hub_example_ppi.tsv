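n11	n02
n11	n05
n11	n08
n11	n09
n11	n16
n11	n17
n03	n08
n07	n18
n14	n16
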