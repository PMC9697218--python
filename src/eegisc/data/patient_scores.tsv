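Code	Age	Sex	Diagnosis	Paresis	CNS Damage	DMD	GMD	Attention	Auditory Memory	Visual Memory	Story
P1	8	F	OBPL	4	3	4	7	5	5	6	4
P2	6	M	AMC	3	2	3	5	1	3	4	2
P3	15	F	OBPL	4	3	3	6	3	6	3	4
P4	5	F	AMC	1	3	3	6	3	3	6	3
P5	9	F	OBPL	4	3	3	6	3	5	3	4
P6	7	M	AMC	1	2	2	6	3	4	2	4
P7	4	M	AMC	1	3	2	5	4	3	3	4
P8	8	F	AMC	1	2	1	3	2	3	3	3
P9	13	M	OBPL	4	3	4	12	5	7	10	2
P10	5	M	OBPL	4	4	4	13	3	5	6	1
P11	4	F	AMC	1	3	2	5	3	5	5	3
P12	10	F	OBPL	4	3	4	11	3	7	6	2
P13	8	F	AMC	1	2	3	5	2	4	3	4
P14	4	F	AMC	1	1	1	2	1	1	4	1
P15	8	M	AMC	1	2	2	4	2	4	5	3
P16	8	M	OBPL	4	3	4	12	3	6	6	3
P17	15	M	AMC	1	2	2	4	4	6	7	3
P18	5	M	AMC	1	2	2	4	2	3	2	1
P19	9	F	AMC	1	1	2	3	2	5	6	3
P20	14	M	OBPL	4	3	4	12	5	7	9	4
P21	8	M	AMC	1	2	1	3	2	3	5	3
P22	5	M	AMC	1	3	3	8	3	5	2	2
P23	9	F	AMC	1	3	3	6	3	7	4	5
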