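>seq1 synthetic dna descendant (seed=11)
AATCGGGACACTGAAATTTGTGCAGCGCCTACTAGCATTTGTTCACGTCTCTGGCGTTTT
A
>seq2 synthetic dna descendant (seed=11)
AATCGGGTCACTGAGATTTGTCAGCGTCTTCTAGCGTTTGTTAAAGTCTCTGGAGTTTTA
>seq3 synthetic dna descendant (seed=11)
AATCGCGACACTCAGACTTTTGTCAACGTCTACTACGTTTGTTAACGTATCTGGAGTTTT
A
>seq4 synthetic dna descendant (seed=11)
AATCGGGACACTGAGATTTGTCAGCGTCTACTAGCGTTTGTCAACGTCACTGGAGTTTTA
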