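family	disease	gene	mat_allele1	mat_allele2	pat_allele1	pat_allele2	fetus_mat	fetus_pat	ga	ff_pct
F01	beta-thalassemia	HBB	c.316-197C>T	N	c.-78A>G	N	N	N	12+4	9.3
F02	beta-thalassemia	HBB	c.126_129delCTTT	N	c.126_129delCTTT	N	N	N	20+5	15.9
F03	beta-thalassemia	HBB	c.126_129delCTTT	N	c.-78A>G	N	c.126_129delCTTT	c.-78A>G	12+3	15.4
F04	beta-thalassemia	HBB	c.316-197C>T	N	c.126_129delCTTT	N	N	c.126_129delCTTT	18	12.1
F05	beta-thalassemia	HBB	c.126_129delCTTT	N	c.316-197C>T	N	c.126_129delCTTT	N	13+6	20.6
F06	beta-thalassemia	HBB	c.216_217insA/T	N	c.126_129delCTTT	N	c.216_217insA/T	c.126_129delCTTT	13+2	26.8
F07	beta-thalassemia	HBB	c.79G>A	N	c.126_129delCTTT	N	N	c.126_129delCTTT	11+3	12.3
F08	beta-thalassemia	HBB	c.126_129delCTTT	N	c.316-197C>T	N	c.126_129delCTTT	N	12+3	16.5
F09	beta-thalassemia	HBB	c.52A>T	N	c.84_85insC	N	c.52A>T	N	12+1	27.7
F10	beta-thalassemia	HBB	c.126_129delCTTT	N	c.79G>A	N	c.126_129delCTTT	c.79G>A	11+1	17.7
F11	beta-thalassemia	HBB	c.126_129delCTTT	N	c.126_129delCTTT	N	c.126_129delCTTT	c.126_129delCTTT	17	8.1
F12	beta-thalassemia	HBB	c.126_129delCTTT	N	c.126_129delCTTT	N	N	c.126_129delCTTT	17	9.7
F13	alpha-thalassemia	HBA	--SEA	N	--SEA	N	--SEA	--SEA	13+3	15.7
F14	alpha-thalassemia	HBA	--SEA	N	--SEA	N	N	N	11+6	13.7
F15	alpha-thalassemia	HBA	--SEA	N	--SEA	N	N	--SEA	12+4	17.5
F16	alpha-thalassemia	HBA	--SEA	N	--SEA	N	--SEA	--SEA	11+3	23.5
F17	alpha-thalassemia	HBA	--SEA	N	c.369C>G	N	--SEA	c.369C>G	18	6.7
F18	MMA	MMACHC	c.609G>A	N	c.609G>A	N	c.609G>A	N	19	16.5
F19	MMA	MMACHC	c.656-658delAGA	N	c.609G>A	N	N	c.609G>A	18	14.2
F20	MMA	MMACHC	c.609G>A	N	c.656-658delAGA	N	N	N	16	12.8
F21	MMA	MMACHC	c.656-658delAGA	N	c.609G>A	N	N	N	17	10.4
F22	MMA	MMACHC	c.80A>G	N	c.609G>A	N	c.80A>G	N	17	10.2
F23	MMA	MMACHC	c.609G>A	N	c.441TG[2]	N	c.609G>A	c.441TG[2]	17	10.1
F24	MMA	MMACHC	c.609G>A	N	c.609G>A	N	N	N	18	17.8
F25	MMA	MMACHC	c.80A>G	N	c.609G>A	N	N	N	17	13.7
F26	MMA	MMACHC	c.609G>A	N	c.658-660delAAG	N	c.609G>A	c.658-660delAAG	17	9.8
F27	MMA	MMACHC	c.609G>A	N	c.445-446delTG	N	N	N	17	10.4
F28	MMA	MMACHC	c.482G>A	N	c.445-446delTG	N	N	N	17	8.2
F29	MMA	MMACHC	c.315C>G	N	c.609G>A	N	c.315C>G	N	16	6.5
F30	MMA	MMACHC	c.609G>A	N	c.609G>A	N	N	N	17+5	8.0
F31	PKU	PAH	c.1197A>T	N	c.764T>C	N	c.1197A>T	c.764T>C	18	7.3
F32	PKU	PAH	c.992T>C	N	c.770G>T	N	N	c.770G>T	17	7.5
F33	PKU	PAH	c.1045T>G	N	c.728G>A	N	N	N	18	11.3
F34	PKU	PAH	c.728G>A	N	c.611A>G	N	N	N	20	5.9
F35	PKU	PAH	c.977G>A	N	c.1238G>C	N	c.977G>A	N	17	21.2
F36	PKU	PAH	c.473G>A	N	c.208_210delTCT	N	c.473G>A	c.208_210delTCT	18	12.8
F37	PKU	PAH	c.1223G>A	N	c.727C>T	N	N	N	12	8.5
F38	PKU	PAH	c.728G>A	N	c.721C>T	N	c.728G>A	c.721C>T	12	7.2
F39	ARPKD	PKHD1	c.11042T>G	N	c.5137G>T	N	N	c.5137G>T	12+6	15.0
F40	DFNB1A	GJB2	c.235delC	N	c.299-300delAT	N	c.235delC	N	13+1	15.3
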