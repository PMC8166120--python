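label	x	y	z	diameter
retrosplenial	2	-48	24	12
l_post_hippocampus	-26	-30	-10	12
r_post_hippocampus	26	-30	-10	12
l_dorsal_anterior_insula	-32	20	2	12
r_dorsal_anterior_insula	36	20	-2	12
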