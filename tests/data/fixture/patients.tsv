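patient_id	age	days_all_abx	days_treatment_abx	n_antibiotics	pip_tazo_gt72h	cefepime_gt72h	carbapenem_gt72h	chemo_category	infection_during_ic	infection_90d_post	remission
P01	37.0	36.0	4.0	6	True	False	True	non_fludarabine_high_intensity	clinical	True	False
P02	60.0	32.0	24.0	3	True	False	True	non_fludarabine_high_intensity	clinical	False	True
P03	55.0	30.0	17.0	5	False	False	False	other	clinical	True	True
P04	71.0	33.0	5.0	2	False	True	True	other	MDI	True	False
P05	61.0	26.0	7.0	2	True	True	True	hypomethylator	clinical	False	True
P06	42.0	29.0	24.0	7	True	False	True	fludarabine	none	False	False
P07	37.0	36.0	17.0	4	False	False	False	fludarabine	MDI	True	True
P08	60.0	24.0	13.0	4	False	False	True	fludarabine	none	True	False
P09	58.0	24.0	12.0	7	False	False	True	fludarabine	none	True	False
P10	63.0	21.0	21.0	8	False	True	True	fludarabine	none	False	False
P11	61.0	27.0	5.0	3	True	False	False	non_fludarabine_high_intensity	none	False	True
P12	58.0	30.0	8.0	2	False	True	True	fludarabine	MDI	True	False
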