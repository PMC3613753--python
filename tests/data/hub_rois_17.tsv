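label	network	x	y	z
ACC_19	Cingulo-opercular	-2	30	27
aPFC_23	Cingulo-opercular	27	49	26
BasalGanglia_24	Cingulo-opercular	14	6	7
BasalGanglia_25	Cingulo-opercular	-20	6	7
Thalamus_43	Cingulo-opercular	-12	-3	13
Thalamus_44	Cingulo-opercular	-12	-12	6
Thalamus_45	Cingulo-opercular	11	-12	6
ACC_51	Default	9	39	20
aPFC_54	Default	-25	51	27
vmPFC_83	Default	-11	45	17
MidInsula_131	Sensorimotor	-42	-3	11
MidInsula_132	Sensorimotor	-36	-12	15
MidInsula_133	Sensorimotor	33	-12	16
vFC_159	Sensorimotor	43	1	12
vFC_160	Sensorimotor	-55	7	23
Precuneus_72	Default	5	-50	33
Precuneus_76	Default	-6	-56	29
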