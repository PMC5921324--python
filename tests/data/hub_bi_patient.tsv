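region	cortex_class	bi
Right superior temporal gyrus	Association	6.87
Right inferior temporal gyrus	Association	3.96
Right middle temporal gyrus	Association	3.62
Left middle temporal gyrus	Association	3.52
Right temporal pole, superior temporal gyrus	Paralimbic	3.44
Left insula	Association	3.19
Left heschl gyrus	Association	3.04
Right fusiform gyrus	Association	2.86
Left inferior parietal, but supramarginal and angular gyri	Association	2.64
Left middle frontal gyrus	Association	2.55
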