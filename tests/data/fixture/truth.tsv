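patient_id	variable	sigma_base	sigma_oral	sigma_stool	days_all_abx	infection_during_ic	infection_90d_post
P01	False	0.15	1.5979484713537613	0.1383353211862017	36.0	True	True
P02	True	0.5	1.529594298153319	0.43374288027208147	32.0	True	False
P03	False	0.15	0.6189051301839	0.1791856361268848	30.0	True	True
P04	False	0.15	0.5790231771563283	0.11144199837364423	33.0	True	True
P05	False	0.15	0.12660963291749452	0.13503744679985666	26.0	True	False
P06	False	0.15	0.3086471332915868	0.16786473244564995	29.0	False	False
P07	True	0.5	5.350974309431837	0.5644831328860606	36.0	True	True
P08	False	0.15	0.10693111571877473	0.18125041094235042	24.0	False	True
P09	False	0.15	0.11753809371831793	0.2218895372187615	24.0	False	True
P10	False	0.15	0.0464890823895885	0.1562839507768145	21.0	False	False
P11	False	0.15	0.12443844896630385	0.1014466686683549	27.0	False	False
P12	True	0.5	1.552591773136639	0.36972793280113114	30.0	True	True
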