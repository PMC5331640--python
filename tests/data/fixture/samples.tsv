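sample_id	patient_id	site	day	order
P01_O01	P01	oral	-2	1
P01_O02	P01	oral	1	2
P01_O03	P01	oral	4	3
P01_O04	P01	oral	9	4
P01_O05	P01	oral	14	5
P01_O06	P01	oral	19	6
P01_O07	P01	oral	24	7
P01_O08	P01	oral	27	8
P01_O09	P01	oral	31	9
P01_S01	P01	stool	-2	1
P01_S02	P01	stool	1	2
P01_S03	P01	stool	4	3
P01_S04	P01	stool	8	4
P01_S05	P01	stool	12	5
P01_S06	P01	stool	16	6
P02_O01	P02	oral	-1	1
P02_O02	P02	oral	4	2
P02_O03	P02	oral	7	3
P02_O04	P02	oral	12	4
P02_O05	P02	oral	16	5
P02_O06	P02	oral	21	6
P02_O07	P02	oral	24	7
P02_O08	P02	oral	27	8
P02_O09	P02	oral	30	9
P02_S01	P02	stool	-1	1
P02_S02	P02	stool	2	2
P02_S03	P02	stool	7	3
P02_S04	P02	stool	10	4
P02_S05	P02	stool	14	5
P02_S06	P02	stool	17	6
P03_O01	P03	oral	0	1
P03_O02	P03	oral	4	2
P03_O03	P03	oral	7	3
P03_O04	P03	oral	12	4
P03_O05	P03	oral	16	5
P03_O06	P03	oral	19	6
P03_O07	P03	oral	22	7
P03_O08	P03	oral	26	8
P03_O09	P03	oral	30	9
P03_S01	P03	stool	0	1
P03_S02	P03	stool	4	2
P03_S03	P03	stool	8	3
P03_S04	P03	stool	12	4
P03_S05	P03	stool	15	5
P03_S06	P03	stool	19	6
P04_O01	P04	oral	-1	1
P04_O02	P04	oral	3	2
P04_O03	P04	oral	8	3
P04_O04	P04	oral	13	4
P04_O05	P04	oral	16	5
P04_O06	P04	oral	19	6
P04_S01	P04	stool	-1	1
P04_S02	P04	stool	4	2
P04_S03	P04	stool	7	3
P04_S04	P04	stool	12	4
P04_S05	P04	stool	16	5
P04_S06	P04	stool	20	6
P05_O01	P05	oral	-1	1
P05_O02	P05	oral	3	2
P05_O03	P05	oral	8	3
P05_O04	P05	oral	11	4
P05_O05	P05	oral	14	5
P05_O06	P05	oral	17	6
P05_O07	P05	oral	21	7
P05_O08	P05	oral	26	8
P05_O09	P05	oral	31	9
P05_S01	P05	stool	0	1
P05_S02	P05	stool	4	2
P05_S03	P05	stool	8	3
P05_S04	P05	stool	11	4
P05_S05	P05	stool	16	5
P05_S06	P05	stool	19	6
P05_S07	P05	stool	23	7
P05_S08	P05	stool	26	8
P05_S09	P05	stool	31	9
P06_O01	P06	oral	-1	1
P06_O02	P06	oral	4	2
P06_O03	P06	oral	7	3
P06_O04	P06	oral	12	4
P06_O05	P06	oral	16	5
P06_O06	P06	oral	21	6
P06_O07	P06	oral	25	7
P06_S01	P06	stool	0	1
P06_S02	P06	stool	5	2
P06_S03	P06	stool	9	3
P06_S04	P06	stool	14	4
P06_S05	P06	stool	17	5
P06_S06	P06	stool	21	6
P06_S07	P06	stool	24	7
P07_O01	P07	oral	0	1
P07_O02	P07	oral	4	2
P07_O03	P07	oral	8	3
P07_O04	P07	oral	13	4
P07_O05	P07	oral	18	5
P07_O06	P07	oral	22	6
P07_O07	P07	oral	26	7
P07_O08	P07	oral	30	8
P07_S01	P07	stool	-2	1
P07_S02	P07	stool	1	2
P07_S03	P07	stool	6	3
P07_S04	P07	stool	11	4
P07_S05	P07	stool	16	5
P07_S06	P07	stool	19	6
P07_S07	P07	stool	22	7
P07_S08	P07	stool	25	8
P07_S09	P07	stool	28	9
P08_O01	P08	oral	-1	1
P08_O02	P08	oral	2	2
P08_O03	P08	oral	5	3
P08_O04	P08	oral	9	4
P08_O05	P08	oral	13	5
P08_O06	P08	oral	18	6
P08_S01	P08	stool	-1	1
P08_S02	P08	stool	3	2
P08_S03	P08	stool	7	3
P08_S04	P08	stool	12	4
P08_S05	P08	stool	15	5
P08_S06	P08	stool	19	6
P09_O01	P09	oral	-1	1
P09_O02	P09	oral	2	2
P09_O03	P09	oral	7	3
P09_O04	P09	oral	10	4
P09_O05	P09	oral	13	5
P09_O06	P09	oral	18	6
P09_O07	P09	oral	21	7
P09_S01	P09	stool	0	1
P09_S02	P09	stool	4	2
P09_S03	P09	stool	7	3
P09_S04	P09	stool	12	4
P09_S05	P09	stool	16	5
P09_S06	P09	stool	19	6
P09_S07	P09	stool	23	7
P10_O01	P10	oral	-2	1
P10_O02	P10	oral	2	2
P10_O03	P10	oral	6	3
P10_O04	P10	oral	10	4
P10_O05	P10	oral	15	5
P10_O06	P10	oral	20	6
P10_O07	P10	oral	23	7
P10_O08	P10	oral	26	8
P10_S01	P10	stool	0	1
P10_S02	P10	stool	5	2
P10_S03	P10	stool	10	3
P10_S04	P10	stool	15	4
P10_S05	P10	stool	18	5
P10_S06	P10	stool	23	6
P10_S07	P10	stool	28	7
P10_S08	P10	stool	32	8
P10_S09	P10	stool	37	9
P11_O01	P11	oral	-1	1
P11_O02	P11	oral	2	2
P11_O03	P11	oral	7	3
P11_O04	P11	oral	11	4
P11_O05	P11	oral	16	5
P11_O06	P11	oral	19	6
P11_S01	P11	stool	0	1
P11_S02	P11	stool	5	2
P11_S03	P11	stool	10	3
P11_S04	P11	stool	14	4
P11_S05	P11	stool	18	5
P11_S06	P11	stool	22	6
P12_O01	P12	oral	-1	1
P12_O02	P12	oral	4	2
P12_O03	P12	oral	7	3
P12_O04	P12	oral	12	4
P12_O05	P12	oral	16	5
P12_O06	P12	oral	20	6
P12_O07	P12	oral	25	7
P12_O08	P12	oral	30	8
P12_O09	P12	oral	34	9
P12_S01	P12	stool	-2	1
P12_S02	P12	stool	1	2
P12_S03	P12	stool	5	3
P12_S04	P12	stool	9	4
P12_S05	P12	stool	13	5
P12_S06	P12	stool	16	6
P12_S07	P12	stool	21	7
P12_S08	P12	stool	26	8
P12_S09	P12	stool	29	9
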