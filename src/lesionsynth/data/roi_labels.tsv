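atlas	label_id	name	hemisphere
HO-Cort	1	frontal pole	L
HO-Cort	2	frontal pole	R
HO-Cort	3	superior frontal gyrus	L
HO-Cort	4	superior frontal gyrus	R
HO-Cort	5	middle frontal gyrus	L
HO-Cort	6	middle frontal gyrus	R
HO-Cort	7	inferior frontal gyrus	L
HO-Cort	8	inferior frontal gyrus	R
HO-Cort	9	precentral gyrus	L
HO-Cort	10	precentral gyrus	R
HO-Cort	11	postcentral gyrus	L
HO-Cort	12	postcentral gyrus	R
HO-Cort	13	anterior cingulate cortex	L
HO-Cort	14	anterior cingulate cortex	R
HO-Cort	15	posterior cingulate cortex	L
HO-Cort	16	posterior cingulate cortex	R
HO-Cort	17	paracingulate gyrus	L
HO-Cort	18	paracingulate gyrus	R
HO-Cort	19	orbitofrontal cortex	L
HO-Cort	20	orbitofrontal cortex	R
HO-Cort	21	frontal medial cortex	L
HO-Cort	22	frontal medial cortex	R
HO-Cort	23	subcallosal cortex	L
HO-Cort	24	subcallosal cortex	R
HO-Cort	25	middle temporal gyrus	L
HO-Cort	26	middle temporal gyrus	R
HO-Cort	27	temporal fusiform cortex posterior	L
HO-Cort	28	temporal fusiform cortex posterior	R
HO-Cort	29	occipital fusiform gyrus	L
HO-Cort	30	occipital fusiform gyrus	R
HO-Cort	31	lingual gyrus	L
HO-Cort	32	lingual gyrus	R
HO-Cort	33	lateral occipital cortex	L
HO-Cort	34	lateral occipital cortex	R
HO-Cort	35	precuneus	L
HO-Cort	36	precuneus	R
HO-Cort	37	angular gyrus	L
HO-Cort	38	angular gyrus	R
HO-Cort	39	insula	L
HO-Cort	40	insula	R
HO-Sub	1	thalamus	L
HO-Sub	2	thalamus	R
HO-Sub	3	caudate	L
HO-Sub	4	caudate	R
HO-Sub	5	putamen	L
HO-Sub	6	putamen	R
HO-Sub	7	pallidum	L
HO-Sub	8	pallidum	R
HO-Sub	9	hippocampus	L
HO-Sub	10	hippocampus	R
HO-Sub	11	amygdala	L
HO-Sub	12	amygdala	R
HO-Sub	13	nucleus accumbens	L
HO-Sub	14	nucleus accumbens	R
HO-Sub	15	ventral diencephalon	L
HO-Sub	16	ventral diencephalon	R
HO-Sub	17	subthalamic nucleus	L
HO-Sub	18	subthalamic nucleus	R
JHU	1	superior longitudinal fasciculus	L
JHU	2	superior longitudinal fasciculus	R
JHU	3	cingulum	L
JHU	4	cingulum	R
Cerebellum	1	cerebellum	L
Cerebellum	2	cerebellum	R
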