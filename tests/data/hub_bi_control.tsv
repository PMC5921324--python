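region	cortex_class	bi
Left inferior frontal gyrus, opercular part	Paralimbic	4.69
Right precuneus	Paralimbic	4.40
Left hippocampus	Paralimbic	4.26
Right inferior frontal gyrus, opercular part	Paralimbic	4.05
Left superior frontal gyrus, orbital part	Paralimbic	3.40
Left fusiform gyrus	Association	3.30
Left superior temporal gyrus	Association	2.79
Right fusiform gyrus	Association	2.67
Left thalamus	Paralimbic	2.24
Right inferior frontal gyrus, triangular part	Association	2.20
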