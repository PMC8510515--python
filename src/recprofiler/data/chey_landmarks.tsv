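# Conserved catalytic landmark residues of E. coli CheY (1-based).
# dd1/dd2: metal-binding acidic pair; d: phosphorylation-site Asp;
# t: Thr/Ser phosphoryl-oxygen contact; k: conserved Lys.
landmark	index
dd1	12
dd2	13
d	57
t	87
k	109
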