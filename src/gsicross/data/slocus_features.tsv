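type	gene	s_haplotype	chromosome	start	end	length	annotation	stamen_fpkm	stamen_se	pistil_fpkm	pistil_se	flags
FBX12	S_C1_FBX12_pseudo	S_C1	Chr3	5391421	5390102	1320	NA					truncated
SLF1	S_C1_SLF1	S_C1	Chr3	5434392	5433145	1248	Chr3g0455861	22	1.6	1	0.4
SLF2	S_C1_SLF2	S_C1	Chr3	5475946	5477154	1209	Chr3g0455891m	18	2.9	1	0.3
S-RNase	S_C1_SRNase	S_C1	Chr3	5498387	5488716	9672	Chr3g0455911m	0	0	100	32
SLF3	S_C1_SLF3	S_C1	Chr3	5559472	5558219	1254	Chr3g0455931m	6	1.9	1	0.1
SLF4	S_C1_SLF4	S_C1	Chr3	5618754	5619992	1239	Chr3g0455991	18	2.8	1	0.2
FBX1	S_C1_FBX1	S_C1	Chr3	5722023	5720695	1329	Chr3g0456091	8	0.8	0	0.2
SLF5	S_C1_SLF5	S_C1	Chr3	5735463	5734183	1281	Chr3g0456131	13	2.5	1	0.2
SLF6	S_C1_SLF6	S_C1	Chr3	5751338	5752606	1269	Chr3g0456171	11	0.5	1	0.2
SLF8	S_C1_SLF8	S_C1	Chr3	5803902	5805158	1257	Chr3g0456241	8	2.4	1	0.3
SLF9	S_C1_SLF9	S_C1	Chr3	5809247	5808021	1227	Chr3g0456251	20	2.6	1	0.4
SLF10	S_C1_SLF10	S_C1	Chr3	5857662	5856391	1272	Chr3g0456291	7	0.6	0	0.3
SLF11	S_C1_SLF11	S_C1	Chr3	5880743	5879523	1221	Chr3g0456311	5	2	1	0.2
FBX4	S_C1_FBX4_pseudo	S_C1	Chr3	5890721	5889444	1278	NA					truncated
FBX2	S_C2_FBX2	S_C2	RC0	27704970	27703705	1266	NA	5	0.6	1	0.2
S-RNase	S_C2_SRNase	S_C2	RC0	27779508	27755726	23783	NA	0	0	44	44
FBX3	S_C2_FBX3	S_C2	RC0	27852918	27854177	1260	RC0G0207600	17	1	1	0.4
SLF7	S_C2_SLF7	S_C2	RC0	27963602	27962373	1230	RC0G0208100m	4	0.7	0	0.1
FBX4	S_C2_FBX4	S_C2	RC3	41290222	41291499	1278	RC3G0342300	16	2.4	1	0.5
SLF11	S_C2_SLF11	S_C2	RC3	41310056	41311276	1221	RC3G0342500	5	0.9	0	0.1
SLF10	S_C2_SLF10	S_C2	RC3	41344314	41345582	1269	RC3G0343000	5	0.5	0	0.2
SLF9	S_C2_SLF9	S_C2	RC3	41348095	41349321	1227	RC3G0343100	18	3.1	1	0.5
SLF8	S_C2_SLF8	S_C2	RC3	41352234	41350978	1257	RC3G0343200	9	2.6	1	0.2
SLF6	S_C2_SLF6_pseudo	S_C2	RC3	41369680	41368410	1271	RC3G0343500m					truncated
SLF5	S_C2_SLF5	S_C2	RC3	41380179	41381417	1239	RC3G0343800m	16	2.8	1	0.3
SLF4	S_C2_SLF4_1	S_C2	RC3	41646962	41648194	1233	RC3G0344900m	4	0.5	0	0
SLF4	S_C2_SLF4_2	S_C2	RC3	41695111	41696343	1233	RC3G0345200	4	1.7	0	0.1
SLF3	S_C2_SLF3	S_C2	RC3	41876741	41877979	1239	RC3G0346100	10	2.8	1	0.2
SLF2	S_C2_SLF2	S_C2	RC3	41896100	41897320	1221	RC3G0346200m	13	2.2	1	0.2
SLF1	S_C2_SLF1	S_C2	RC3	41907657	41908904	1248	RC3G0346300	15	3.1	1	0.2
FBX5	S_C2_FBX5	S_C2	RC3	41932562	41931243	1320	RC3G0346700	4	1.6	1	0.2
FBX12	S_C2_FBX12	S_C2	RC3	41965102	41966437	1336	RC3G0347000m					truncated
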