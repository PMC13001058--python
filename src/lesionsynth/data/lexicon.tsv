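phrase	atlas	label_id
frontal pole	HO-Cort	1
frontal pole	HO-Cort	2
dorsolateral prefrontal cortex	HO-Cort	5
dorsolateral prefrontal cortex	HO-Cort	6
dlpfc	HO-Cort	5
dlpfc	HO-Cort	6
superior frontal gyrus	HO-Cort	3
superior frontal gyrus	HO-Cort	4
sfg	HO-Cort	3
sfg	HO-Cort	4
middle frontal gyrus	HO-Cort	5
middle frontal gyrus	HO-Cort	6
inferior frontal gyrus	HO-Cort	7
inferior frontal gyrus	HO-Cort	8
ifg	HO-Cort	7
ifg	HO-Cort	8
precentral gyrus	HO-Cort	9
precentral gyrus	HO-Cort	10
postcentral gyrus	HO-Cort	11
postcentral gyrus	HO-Cort	12
anterior cingulate cortex	HO-Cort	13
anterior cingulate cortex	HO-Cort	14
acc	HO-Cort	13
acc	HO-Cort	14
dacc	HO-Cort	13
dacc	HO-Cort	14
dorsal anterior cingulate cortex	HO-Cort	13
dorsal anterior cingulate cortex	HO-Cort	14
rostral anterior cingulate cortex	HO-Cort	13
rostral anterior cingulate cortex	HO-Cort	14
posterior cingulate cortex	HO-Cort	15
posterior cingulate cortex	HO-Cort	16
pcc	HO-Cort	15
pcc	HO-Cort	16
paracingulate gyrus	HO-Cort	17
paracingulate gyrus	HO-Cort	18
orbitofrontal cortex	HO-Cort	19
orbitofrontal cortex	HO-Cort	20
ofc	HO-Cort	19
ofc	HO-Cort	20
lateral orbitofrontal cortex	HO-Cort	19
lateral orbitofrontal cortex	HO-Cort	20
medial orbitofrontal cortex	HO-Cort	19
medial orbitofrontal cortex	HO-Cort	20
frontal medial cortex	HO-Cort	21
frontal medial cortex	HO-Cort	22
medial frontal cortex	HO-Cort	21
medial frontal cortex	HO-Cort	22
subcallosal cortex	HO-Cort	23
subcallosal cortex	HO-Cort	24
paraterminal gyrus	HO-Cort	23
paraterminal gyrus	HO-Cort	24
middle temporal gyrus	HO-Cort	25
middle temporal gyrus	HO-Cort	26
temporal fusiform cortex posterior	HO-Cort	27
temporal fusiform cortex posterior	HO-Cort	28
posterior temporal fusiform gyrus	HO-Cort	27
posterior temporal fusiform gyrus	HO-Cort	28
occipital fusiform gyrus	HO-Cort	29
occipital fusiform gyrus	HO-Cort	30
lingual gyrus	HO-Cort	31
lingual gyrus	HO-Cort	32
lateral occipital cortex	HO-Cort	33
lateral occipital cortex	HO-Cort	34
occipital cortex	HO-Cort	33
occipital cortex	HO-Cort	34
precuneus	HO-Cort	35
precuneus	HO-Cort	36
angular gyrus	HO-Cort	37
angular gyrus	HO-Cort	38
insula	HO-Cort	39
insula	HO-Cort	40
thalamus	HO-Sub	1
thalamus	HO-Sub	2
caudate	HO-Sub	3
caudate	HO-Sub	4
dorsal caudate	HO-Sub	3
dorsal caudate	HO-Sub	4
putamen	HO-Sub	5
putamen	HO-Sub	6
dorsal putamen	HO-Sub	5
dorsal putamen	HO-Sub	6
pallidum	HO-Sub	7
pallidum	HO-Sub	8
hippocampus	HO-Sub	9
hippocampus	HO-Sub	10
amygdala	HO-Sub	11
amygdala	HO-Sub	12
nucleus accumbens	HO-Sub	13
nucleus accumbens	HO-Sub	14
nacc	HO-Sub	13
nacc	HO-Sub	14
ventral striatum	HO-Sub	13
ventral striatum	HO-Sub	14
ventral diencephalon	HO-Sub	15
ventral diencephalon	HO-Sub	16
subthalamic nucleus	HO-Sub	17
subthalamic nucleus	HO-Sub	18
stn	HO-Sub	17
stn	HO-Sub	18
superior longitudinal fasciculus	JHU	1
superior longitudinal fasciculus	JHU	2
slf	JHU	1
slf	JHU	2
cingulum	JHU	3
cingulum	JHU	4
cerebellum	Cerebellum	1
cerebellum	Cerebellum	2
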