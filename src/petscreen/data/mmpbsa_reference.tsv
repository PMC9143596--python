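variant	replica	vdw_mean	vdw_sd	electrostatic_mean	electrostatic_sd	polar_mean	polar_sd	apolar_mean	apolar_sd	total_mean	total_sd
WT	r0	-215	35	-38	27	121	25	-25	4	-156	39
WT	r1	-158	53	-55	26	108	44	-19	6	-124	62
Q119F	r0	-160	18	-32	19	94	38	-20	2	-118	38
Q119F	r1	-155	27	-31	35	88	19	-19	3	-116	51
D112M/S238F	r0	-176	45	-30	25	117	24	-21	6	-110	70
D112M/S238F	r1	-159	33	-32	19	116	42	-18	3	-93	46
S238C	r0	-209	36	-53	35	112	31	-24	4	-175	40
S238C	r1	-173	23	-39	33	112	42	-20	3	-121	37
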