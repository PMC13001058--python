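study_id	citation	n_treated	procedure	lesion_modality	imaging_modalities	mixed_cohort	ybocs_pre_mean	ybocs_post_mean
banks2015	Banks et al. (2015)	15	cingulotomy	RF	sMRI;dMRI	False
davidson2020	Davidson et al. (2020)	6	capsulotomy	MRgFUS	rs_fMRI;FDG_PET	True
lv2021	Lv et al. (2021)	31	capsulotomy	RF	sMRI;dMRI	False	31.2	17.8
rauch2001a	Rauch et al. (2001)	11	cingulotomy	RF	FDG_PET	False
yin2018	Yin et al. (2018)	36	capsulotomy	RF	rs_fMRI	False	31.0	15.9
zhang2021	Zhang et al. (2021)	41	capsulotomy	RF	dMRI	False
bingley1978	Bingley and Persson (1978)	35	capsulotomy	RF	EEG	False
bouwens2022	Bouwens van der Vlis et al. (2022)	8	capsulotomy	GK	sMRI;dMRI	False	32.1	18.9
cecconi2008	Cecconi et al. (2008)	5	capsulotomy	GK	sMRI	False	34.0	20.2
chang2003	Chang et al. (2003)	8	cingulotomy	RF	SPECT	False	30.5	19.8
chang2023	Chang et al. (2023)	8	capsulotomy	MRgFUS	MEG	False
chen2022	Chen et al. (2022)	27	capsulotomy	RF	rs_fMRI	False	31.5	17.0
cui2023	Cui et al. (2023)	27	capsulotomy	RF	sMRI;t_fMRI	False	30.8	16.4
hurwitz2020	Hurwitz et al. (2020)	3	capsulotomy	RF	SPECT	True
kim2001	Kim et al. (2001)	8	limbic_leukotomy	RF	SPECT	False	31.8	20.6
liu2008	Liu et al. (2008)	35	capsulotomy	RF	FDG_PET	False	32.4	18.1
liu2017	Liu et al. (2017)	37	capsulotomy	RF	FDG_PET	False	33.0	17.5
mindus1990	Mindus et al. (1990)	5	capsulotomy	RF	FDG_PET	False
rauch2000	Rauch et al. (2000)	9	cingulotomy	RF	sMRI	False	29.6	18.0
rauch2001b	Rauch et al. (2001)	9	cingulotomy	RF	sMRI	False
suetens2014	Suetens et al. (2014)	13	capsulotomy	RF	FDG_PET	False	34.6	20.9
taren1994	Taren et al. (1994)	5	capsulotomy	RF	sMRI	False
zhan2014	Zhan et al. (2014)	53	capsulotomy	RF	FDG_PET	False	32.8	17.3
zuo2013	Zuo et al. (2013)	8	capsulotomy	RF	FDG_PET	False	33.5	19.2
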