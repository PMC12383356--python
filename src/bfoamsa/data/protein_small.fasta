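>seq1 synthetic protein descendant (seed=12)
PGYWCEEENHLFYQQDEVHVSALMLDRGIKGLTLRWFGINEQQQWKWQYVWHPEVTKSF
>seq2 synthetic protein descendant (seed=12)
PGYQCEEYNHLFYQQDEQVHVSALMLDCGIKGLTLRWFGNEQQYQWKWYVHCVWHPEVTN
SF
>seq3 synthetic protein descendant (seed=12)
PGYWCEYENNHLFYQQDEVHVSALMLDRGIKGLTLRWFGNEQQQWKWYVHCSWHPEVTKS
F
>seq4 synthetic protein descendant (seed=12)
FGYWCEEENPLFYQPDEVHVSALMLDRGIKGLTPLRWFGNEQQLWKWYVHIVWHPEVTKS
F
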