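family	sample	gene	chrom	block_start	block_end	block_size_kb	n_snps
F01	mat	HBB	chr11	4249489	6238960	1989.5	2367
F01	pat	HBB	chr11	4269280	5761797	1492.5	1469
F02	mat	HBB	chr11	4366798	6246383	1879.6	1803
F02	pat	HBB	chr11	4366798	6237565	1870.8	1655
F03	mat	HBB	chr11	4249238	5884595	1635.4	1716
F03	pat	HBB	chr11	4346064	6121271	1775.2	1972
F04	mat	HBB	chr11	4587676	6243982	1656.3	2308
F04	pat	HBB	chr11	4905140	6216304	1311.2	1644
F05	mat	HBB	chr11	5192535	5900085	707.6	955
F05	pat	HBB	chr11	4249095	5450493	1201.4	1359
F06	mat	HBB	chr11	4852009	5555972	704.0	741
F06	pat	HBB	chr11	5196669	6082903	886.2	1541
F07	mat	HBB	chr11	4697080	6239344	1542.3	1810
F07	pat	HBB	chr11	4306665	6246051	1939.4	2043
F08	mat	HBB	chr11	4936613	6116142	1179.5	1544
F08	pat	HBB	chr11	4249126	5771915	1522.8	1369
F09	mat	HBB	chr11	4436676	6239344	1802.7	1681
F09	pat	HBB	chr11	4249163	6090372	1841.2	2247
F10	mat	HBB	chr11	4249271	6237565	1988.3	1666
F10	pat	HBB	chr11	4249031	6037803	1788.8	1733
F11	mat	HBB	chr11	4345701	5647166	1301.5	1202
F11	pat	HBB	chr11	4389404	5719251	1329.8	1450
F12	mat	HBB	chr11	4249095	6239344	1990.2	2301
F12	pat	HBB	chr11	4387760	6121428	1733.7	2418
F13	mat	HBA	chr16	60185	679412	619.2	284
F13	pat	HBA	chr16	60185	1225628	1165.4	937
F14	mat	HBA	chr16	186950	1216997	1030.0	606
F14	pat	HBA	chr16	132246	612607	480.4	251
F15	mat	HBA	chr16	94080	1225184	1131.1	899
F15	pat	HBA	chr16	74039	1197612	1123.6	687
F16	mat	HBA	chr16	79811	1223722	1143.9	883
F16	pat	HBA	chr16	60185	460830	400.6	339
F17	mat	HBA	chr16	60185	1192620	1132.4	1045
F17	pat	HBA	chr16	60291	1225184	1164.9	1010
F18	mat	MMACHC	chr1	44966837	46952164	1985.3	1599
F18	pat	MMACHC	chr1	44972309	46972958	2000.6	926
F19	mat	MMACHC	chr1	45513754	46973454	1459.7	440
F19	pat	MMACHC	chr1	44979498	46975877	1996.3	831
F20	mat	MMACHC	chr1	45767431	46206444	439.0	119
F20	pat	MMACHC	chr1	45386861	46503217	1116.3	247
F21	mat	MMACHC	chr1	45765523	46975294	1209.8	457
F21	pat	MMACHC	chr1	44967323	46975877	2008.6	812
F22	mat	MMACHC	chr1	45762749	46722939	960.2	445
F22	pat	MMACHC	chr1	45701916	46097939	396.0	161
F23	mat	MMACHC	chr1	45738336	46975450	1237.1	729
F23	pat	MMACHC	chr1	44967431	46975877	2008.4	1228
F24	mat	MMACHC	chr1	45947353	46095125	147.8	27
F24	pat	MMACHC	chr1	45775550	46605728	830.2	609
F25	mat	MMACHC	chr1	45765523	46053981	288.5	156
F25	pat	MMACHC	chr1	45765523	45982693	217.2	41
F26	mat	MMACHC	chr1	45767431	46975877	1208.4	691
F26	pat	MMACHC	chr1	45762749	46975877	1213.1	684
F27	mat	MMACHC	chr1	45683746	46645681	961.9	572
F27	pat	MMACHC	chr1	45962137	45974407	12.3	3
F28	mat	MMACHC	chr1	44967323	45974520	1007.2	595
F28	pat	MMACHC	chr1	44967323	46691245	1723.9	1149
F29	mat	MMACHC	chr1	45640368	46975877	1335.5	599
F29	pat	MMACHC	chr1	44973546	46975877	2002.3	1185
F30	mat	MMACHC	chr1	44967825	46975877	2008.1	1082
F30	pat	MMACHC	chr1	45683419	46924563	1241.1	685
F31	mat	PAH	chr12	103214192	104013534	799.3	301
F31	pat	PAH	chr12	102252463	104225303	1972.8	1299
F32	mat	PAH	chr12	102241500	104309559	2068.1	1300
F32	pat	PAH	chr12	102240964	104261374	2020.4	1094
F33	mat	PAH	chr12	102240964	103276441	1035.5	555
F33	pat	PAH	chr12	102241500	104173880	1932.4	1048
F34	mat	PAH	chr12	102618568	104309712	1691.1	1095
F34	pat	PAH	chr12	102728895	104272113	1543.2	696
F35	mat	PAH	chr12	102894838	103267467	372.6	136
F35	pat	PAH	chr12	103075411	104309383	1234.0	1069
F36	mat	PAH	chr12	102248565	104275721	2027.2	1189
F36	pat	PAH	chr12	103105959	103274915	169.0	106
F37	mat	PAH	chr12	102321986	103791220	1469.2	984
F37	pat	PAH	chr12	102710699	104300441	1589.7	1062
F38	mat	PAH	chr12	102240964	103623855	1382.9	619
F38	pat	PAH	chr12	102240964	104304705	2063.7	1246
F39	mat	PKHD1	chr6	50968947	52950047	1981.1	1347
F39	pat	PKHD1	chr6	50982112	52905592	1923.5	985
F40	mat	GJB2	chr13	20687773	20802900	115.1	93
F40	pat	GJB2	chr13	20676993	21122165	445.2	279
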