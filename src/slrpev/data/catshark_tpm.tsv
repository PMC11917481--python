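gene	clade	Meckels_cartilage	Vertebrae	Chondrocranium	Skin_denticles	Dental_lamina	Eye	AOL	E-St-12	E-St-22	E-St-24	E-St-26	E-St-30	E-St-31
ecm2	1	63.0	64.9	46.7	18.7	32.6	24.4	45.6	7.5	10.0	13.4	13.2	26.4	19.9
ecm2L	1	1.0	0.9	1.3	0.9	1.3	1.3	1.0	1.0	141.5	182.2	149.2	4.3	1.8
aspn	2	129.2	130.9	54.2	30.0	130.6	33.5	26.5	1.2	1.5	2.6	2.4	33.0	61.6
bgn	2	388.0	711.6	550.2	208.0	170.1	284.1	1048.8	1.0	38.6	119.7	63.1	134.3	121.1
dcn1	2	93.0	244.5	29.9	22.9	33.0	4.1	7.4	3.5	2.2	6.2	8.6	50.6	72.7
dcn2	2	2.1	2.5	1.0	0.5	0.5	4.5	0.5	0.2	0.5	0.5	0.9	5.9	11.0
fmod	3	144.7	305.2	56.1	6.4	7.6	7.1	6.5	6.0	6.3	12.1	9.9	16.8	8.8
kera	3	4.5	4.3	3.6	4.3	5.2	4.8	3.7	2.9	5.3	9.0	15.6	48.7	31.1
lum	3	688.7	825.9	259.9	93.6	211.3	51.2	268.6	1.0	16.1	8.6	24.4	119.1	189.0
omd	3	33.4	31.1	26.3	21.6	32.9	17.8	22.8	14.8	13.8	17.3	16.2	93.3	133.3
prelp	3	118.5	222.6	124.0	59.6	48.5	71.6	103.8	9.5	17.1	18.9	19.5	51.3	44.7
epyc	4	199.1	1939.3	46.1	1.9	2.6	9.0	2.9	1.3	42.6	39.4	49.2	43.5	16.1
ogn	4	152.1	246.9	136.9	58.7	39.5	55.4	70.8	1.3	1.6	2.8	2.7	91.8	129.3
chad1	non-canonical	1325.9	2715.1	704.3	12.0	4.0	57.7	9.8	0.5	0.4	0.9	3.2	37.9	21.3
chad2	non-canonical	234.7	152.7	90.1	0.5	1.8	9.5	3.3	1.2	3.9	4.2	6.9	17.4	10.0
chad3	non-canonical	9.5	7.4	15.2	9.9	6.6	13.9	11.0	1.8	6.1	9.4	8.7	10.6	11.5
npc	non-canonical	0.1	0.1	0.1	0.0	0.0	0.0	0.1	0.1	0.9	1.1	1.7	0.1	0.1
nyx	non-canonical	2.7	2.7	2.6	2.0	2.8	5.7	2.2	1.3	2.1	3.1	2.2	3.3	2.6
podn1	non-canonical	9.5	13.6	17.4	1.1	1.7	9.0	8.2	0.3	0.7	1.7	3.4	10.3	8.9
podn2	non-canonical	40.7	32.0	24.3	14.0	16.2	18.0	10.1	9.6	11.1	13.9	11.8	12.3	10.3
tsku	non-canonical	21.6	15.0	18.6	33.4	50.3	36.1	11.9	22.1	23.0	15.3	26.0	23.0	20.2
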