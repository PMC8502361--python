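family	gene	n_mat_informative	n_pat_informative	cs_mat_pct	cs_pat_pct	nipd_mat	nipd_pat	invasive_mat	invasive_pat
F01	HBB	1260	305	100	100	N	N	N	N
F02	HBB	1073	607	100	100	N	N	N	N
F03	HBB	521	566	100	100	c.126_129delCTTT	c.-78A>G	c.126_129delCTTT	c.-78A>G
F04	HBB	394	317	100	100	N	c.126_129delCTTT	N	c.126_129delCTTT
F05	HBB	255	555	100	100	c.126_129delCTTT	N	c.126_129delCTTT	N
F06	HBB	268	453	100	100	c.216_217insA/T	c.126_129delCTTT	c.216_217insA/T	c.126_129delCTTT
F07	HBB	697	695	100	100	N	c.126_129delCTTT	N	c.126_129delCTTT
F08	HBB	636	442	100	100	c.126_129delCTTT	N	c.126_129delCTTT	N
F09	HBB	669	553	100	100	c.52A>T	N	c.52A>T	N
F10	HBB	908	594	100	100	c.126_129delCTTT	c.79G>A	c.126_129delCTTT	c.79G>A
F11	HBB	603	380	100	100	c.126_129delCTTT	c.126_129delCTTT	c.126_129delCTTT	c.126_129delCTTT
F12	HBB	1029	550	100	100	N	c.126_129delCTTT	N	c.126_129delCTTT
F13	HBA	53	18	100	100	--SEA	--SEA	--SEA	--SEA
F14	HBA	235	52	100	100	N	N	N	N
F15	HBA	118	84	100	100	N	--SEA	N	--SEA
F16	HBA	193	78	100	100	--SEA	--SEA	--SEA	--SEA
F17	HBA	361	140	100	100	--SEA	c.369C>G	--SEA	c.369C>G
F18	MMACHC	775	228	100	100	c.609G>A	N	c.609G>A	N
F19	MMACHC	298	424	100	100	N	c.609G>A	N	c.609G>A
F20	MMACHC	97	175	100	100	N	N	N	N
F21	MMACHC	348	361	100	100	N	N	N	N
F22	MMACHC	285	49	100	100	c.80A>G	N	c.80A>G	N
F23	MMACHC	531	300	100	100	c.609G>A	c.441TG[2]	c.609G>A	c.441TG[2]
F24	MMACHC	154	20	100	100	N	N	N	N
F25	MMACHC	79	7	100	100	N	N	N	N
F26	MMACHC	492	107	100	100	c.609G>A	c.658-660delAAG	c.609G>A	c.658-660delAAG
F27	MMACHC	353	NA	100	NA	N	NA	N	N
F28	MMACHC	474	457	100	100	N	N	N	N
F29	MMACHC	319	469	100	100	c.315C>G	N	c.315C>G	N
F30	MMACHC	776	42	100	100	N	N	N	N
F31	PAH	69	321	100	100	c.1197A>T	c.764T>C	c.1197A>T	c.764T>C
F32	PAH	362	185	100	100	N	c.770G>T	N	c.770G>T
F33	PAH	161	147	100	100	N	N	N	N
F34	PAH	262	95	100	100	N	N	N	N
F35	PAH	131	74	100	100	c.977G>A	N	c.977G>A	N
F36	PAH	188	NA	100	NA	NC	NA	c.473G>A	c.208_210delTCT
F37	PAH	261	164	100	100	N	N	N	N
F38	PAH	406	561	100	100	c.728G>A	c.721C>T	c.728G>A	c.721C>T
F39	PKHD1	971	267	100	100	N	c.5137G>T	N	c.5137G>T
F40	GJB2	29	53	100	100	c.235delC	N	c.235delC	N
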