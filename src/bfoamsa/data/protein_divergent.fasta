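>seq1 synthetic protein descendant (seed=13)
VVDRCTWGECSWPPSRTWDYTWGLTWCQKHTQKVMVDWTMLHFGSIYIMKRIYPAYNGNG
A
>seq2 synthetic protein descendant (seed=13)
VNTVCTWGECSQPSATWDYPGLGWCQPPTQLVMVDWTMLHWGSQVRMYPIYNGNGD
>seq3 synthetic protein descendant (seed=13)
MVTDCTVWGTCSWPPSATQDYTDLTHCQQKVVEVCWTMLGFGSIYRMIRIFWGYNQNQD
>seq4 synthetic protein descendant (seed=13)
VVTWCSWPECSSWVPIATWDYTGLTWCFHTQAVMVDWTSLHCSIYIMIRIEPAYNQYSD
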