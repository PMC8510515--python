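>CheY_Ecoli chemotaxis response regulator CheY, Escherichia coli K-12 (UniProt P0AE67; structure 1FQW)
MADKELKFLVVDDFSTMRRIVRNLLKELGFNNVEEAEDGVDALNKLQAGGYGFVISDWNM
PNMDGLELLKTIRADGAMSALPVLMVTAEAKKENIIAAAQAGASGYVVKPFTAATLEEKL
NKIFEKLGM
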