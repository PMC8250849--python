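taxon	total_length	gc_content	helix_I	helix_II	helix_III	n_gu_pairs	delta_g
Almophrya bivacuolata	154	44.81	19	26	75	4	-43.2
Anoplophrya allolobophorae	160	57.50	25	27	84	4	-49.6
Anoplophrya aporrectodeae	160	56.25	25	27	84	5	-50.5
Anoplophrya lumbrici	163	47.85	21	26	80	3	-43.9
Anoplophrya octolasionis	161	49.07	25	26	80	3	-44.6
Anoplophrya vulgaris	156	54.49	24	24	78	5	-41.0
Eudrilophrya complanata	158	42.41	19	26	76	3	-29.5
Metaracoelophrya sp.	157	33.12	20	26	74	3	-35.3
Metaradiophrya chlorotica	164	49.39	25	28	85	7	-42.9
Metaradiophrya lumbrici	160	43.13	25	24	89	8	-41.6
Metaradiophrya speculorum	162	45.68	25	26	85	8	-40.4
Metaradiophrya varians	165	42.42	25	29	89	9	-43.3
Maupasella mucronata	162	43.83	27	27	92	6	-35.5
Njinella prolifera	160	48.75	23	26	83	3	-32.9
Paraclausilocola constricta	155	47.10	19	25	74	3	-34.5
Subanoplophrya nodulata	166	34.94	0	28	81	4	-42.7
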