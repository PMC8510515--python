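# Secondary-structure intervals for E. coli CheY (1-based, inclusive).
# Approximate assignment from the BeF3-activated CheY structure (PDB 1FQW);
# boundaries placed so each conserved catalytic residue sits at the strand
# position described for the (beta-alpha)5 receiver-domain fold.
element	start	end
b1	8	13
a1	18	29
b2	33	37
a2	41	48
b3	52	57
a3	64	75
b4	82	87
a4	91	100
b5	105	110
a5	113	127
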