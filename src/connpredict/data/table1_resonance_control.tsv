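region_name	atlas_id	network	x_mm	y_mm	z_mm
Inferior frontal gyrus pars opercularis	207	resonance	48	22	10
Inferior frontal gyrus pars opercularis	176	resonance	-47	11	23
Anterior insula	208	resonance	-35	20	0
Anterior insula	209	resonance	36	22	3
Primary motor cortex	36	resonance	42	-20	55
Primary motor cortex	29	resonance	44	-8	57
Primary motor cortex	24	resonance	-40	-19	54
Primary motor cortex	37	resonance	-38	-15	69
Primary somatosensory cortex	27	resonance	-38	-27	69
Primary somatosensory cortex	26	resonance	50	-20	42
Primary somatosensory cortex	46	resonance	66	-8	25
Primary somatosensory cortex	45	resonance	-53	-10	24
Inferior parietal lobule	33	resonance	-45	-32	47
Inferior parietal lobule	190	resonance	49	-42	45
Inferior parietal lobule	255	resonance	47	-30	49
Inferior parietal lobule	259	resonance	-33	-46	47
Superior parietal lobule	30	resonance	-29	-43	61
Superior parietal lobule	25	resonance	29	-39	59
Superior parietal lobule	22	resonance	10	-46	73
Superior parietal lobule	32	resonance	22	-42	69
Superior parietal lobule	38	resonance	-16	-46	73
Superior parietal lobule	34	resonance	-21	-31	61
Premotor cortex	261	resonance	-32	-1	54
Premotor cortex	205	resonance	42	0	47
Premotor cortex	264	resonance	29	-5	54
Premotor cortex	174	resonance	-44	2	46
Parahippocampal gyrus	125	resonance	27	-37	-13
Parahippocampal gyrus	126	resonance	-34	-38	-16
Amygdala		resonance	-22	-6	-14
Amygdala		resonance	22	-6	-14
Superior temporal sulcus	236	resonance	-56	-50	10
Superior temporal sulcus	238	resonance	52	-33	8
Superior temporal sulcus	240	resonance	56	-46	11
Superior temporal sulcus	237	resonance	-55	-40	14
Medial prefrontal/cingulate cortex	54	control	7	8	51
Medial prefrontal/cingulate cortex	47	control	-3	2	53
Medial prefrontal/cingulate cortex	213	control	-1	15	44
Medial prefrontal/cingulate cortex	202	control	-3	26	44
Medial prefrontal/cingulate cortex	112	control	-2	38	36
Medial prefrontal/cingulate cortex	115	control	-8	48	23
Medial prefrontal/cingulate cortex	113	control	-3	42	16
Medial prefrontal/cingulate cortex	75	control	6	67	-4
Medial prefrontal/cingulate cortex	216	control	5	23	37
Medial prefrontal/cingulate cortex	105	control	6	54	16
Medial prefrontal/cingulate cortex	106	control	6	64	22
Medial prefrontal/cingulate cortex	108	control	9	54	3
Dorsolateral prefrontal cortex	100	control	-35	20	51
Dorsolateral prefrontal cortex	193	control	32	14	56
Dorsolateral prefrontal cortex	196	control	40	18	40
Dorsolateral prefrontal cortex	201	control	-42	25	30
Temporoparietal junction	79	control	-46	-61	21
Temporoparietal junction	204	control	55	-45	37
Temporoparietal junction	86	control	-44	-65	35
Temporoparietal junction	235	control	54	-43	22
Orbitofrontal cortex	139	control	49	35	-12
Orbitofrontal cortex	137	control	-46	31	-13
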