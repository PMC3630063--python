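name	mature_sequence	counts	location	arm	lp_nt	mef_kcal_mol	found_by
Ptc-miRn1	CUGUUAUGAAUUGAUGGAGUG	71(10)	scaffold_14:13399032:13399142:-	3'	111	-56.3	
Ptc-miRn2	UGGUAAUGCAAGUGUUGCUAA	22(15)	scaffold_11:1025164:1025342:+	3'	179	-67.2	
Ptc-miRn3	UAGAUUGUUUUUAUGCUUUGA	19(2)	scaffold_16:10809578:10809788:+	5'	211	-106.5	D
Ptc-miRn4	CUCUUCAAAUAAAUCGUGGGA	380(12)	scaffold_4:10873191:10873312:-	3'	122	-66.8	
Ptc-miRn5	AAUGUUGUUAUUAACACUGUA	127(27)	scaffold_4:20884831:20884933:+	3'	103	-48.2	
Ptc-miRn6a	UUAUGCAUUUUUGUCCCUCGC	171(1)	scaffold_4:2221707:2221834:+	3'	128	-64.5	
Ptc-miRn6b	UUAUGCAUUUUUGUCCCUCGC	171(52)	scaffold_5:24265933:24266061:+	3'	129	-63.2	F
Ptc-miRn6c	UUAUGCAUUUUUGUCCCUCGC	171(49)	scaffold_5:24270121:24270264:+	3'	144	-67.7	
Ptc-miRn6d	UUAUGCAUUUUUGUCCCUCGC	171(1)	scaffold_5:24280115:24280237:+	3'	123	-51.6	F
Ptc-miRn7a	UCUUAUGCGUUUUUGUCUCU	238(3)	scaffold_5:24266243:24266355:+	3'	113	-60.7	D
Ptc-miRn7b	UCUUAUGCGUUUUUGUCUCU	238(26)	scaffold_5:24270440:24270552:+	3'	113	-61.6	CD
Ptc-miRn8	UUUGGUUAUUGUCUCGAGACA	1664(23)	scaffold_15:1581044:1581277:-	5'	234	-95.6	
Ptc-miRn9	UUUCUUAUCGAUCACUAGACG	41(1)	scaffold_1112:3373:3393:+	3'	116	-54.4	
Ptc-miRn10	UCUCUUCUGUUCCUGAACGGU	16(7)	scaffold_1:15618173:15618365:+	3'	193	-63.4	
Ptc-miRn11	UUGCUGAAACGAUUGAACUAU	70(2)	scaffold_9:10835006:10835091:+	3'	86	-48.6	E
Ptc-miRn12	UCUUGAGAACAUGAUGAAUCG	11(1)	scaffold_11:4410758:4410914:+	5'	157	-57.7	
Ptc-miRn13	UGAUGAUUAAUUGACUGCAAA	754(51)	scaffold_1:34025510:34025606:+	5'	97	-60.1	E
Ptc-miRn14	AUCAUAUAGGUUGAUCCUCGU	18(1)	scaffold_6:6189111:6189190:-	5'	80	-58.6	
Ptc-miRn15	UCUGUCGCUGGAAAGAUGGUAC	57000(57)	scaffold_17:10902829:10902928:+	5'	100	-66.7	AE
Ptc-miRn16	AGAUGGGCAUCGGCAUUGUGA	116(7)	scaffold_13:797593:797704:-	3'	112	-48.9	
Ptc-miRn17	CGCUCGCCAGCGUUGCACCACC	618(247)	scaffold_1:10455697:10455799:-	5'	103	-47.3	E
Ptc-miRn18	UUUGAAAUUGAACAAAUGGUA	10(1)	scaffold_5:17113917:17114027:+	5'	111	-64.6	
Ptc-miRn19	UUGCAUGCAUGAACUUGAAAU	178(4)	scaffold_4:20393549:20393757:+	3'	209	-81.1	B
Ptc-miRn20	UUGAGAAAAGUCAAUCGGACC	11(1)	scaffold_13:7256997:7257111:-	5'	115	-48.5	
Ptc-miRn21	UGUUCAGAUCAGUAGAUAGCA	1310(29)	scaffold_8:207741:207864:-	5'	124	-46.6	BE
Ptc-miRn22	UAGAGCAGAUUGUAAGGGAAG	528793(209)	scaffold_1:5198865:5198974:-	3'	110	-49.3	CDE
Ptc-miRn23	UUGAAGAAAGGUAGACAGAUAG	207(1)	scaffold_3:14589106:14589377:-	3'	272	-74.3	D
Ptc-miRn24a	CGAACGUUGACCGAAUGUGAA	15(3)	scaffold_10:11417598:11417684:-	5'	87	-31.9	
Ptc-miRn24b	CGAACGUUGACCGAAUGUGAA	15(3)	scaffold_1646:4003:4023:+	5'	88	-35.4	
Ptc-miRn25	UUGUACACAGAAUAGGUGAAAU	1624(7)	scaffold_5:1237647:1237753:+	3'	107	-35.4	CE
Ptc-miRn26	UUACCAAGUUUCAAAUUCUCA	8(5)	scaffold_16:2500220:2500318:-	5'	99	-53.1	
Ptc-miRn27	GCUAGGACCAAGUUUUUUGGA	367(50)	scaffold_13:9970810:9970906:+	5'	97	-58	
Ptc-miRn28	GAUGACAUGGACACCAAAAUC	9(6)	scaffold_1:35822741:35822925:-	5'	185	-64	
Ptc-miRn29	ACACAGAAACUCCAAGCCCAC	48(2)	scaffold_15:14059579:14059742:-	3'	164	-88.4	
Ptc-miRn30	UGAUCUAGAGAACCGUUGCU	38(3)	scaffold_15:5977842:5977957:+	5'	116	-54.5	
Ptc-miRn31	UACAUGUAGAGACCACCAAAC	75(51)	scaffold_10:2022789:2023023:+	5'	235	-97.1	
Ptc-miRn32	UGUCGCAGGAGAGAUGGCGCUA	216(21)	scaffold_17:10888890:10889033:+	5'	144	-67.8	D
Ptc-miRn33	UAGUUCCCAACCUACACCACA	6(2)	scaffold_12:5445549:5445646:+	5'	98	-63.8	
Ptc-miRn34	UAAUUAGAACUCAUACUAGAC	44(4)	scaffold_13:3364782:3364868:+	5'	87	-38.6	
Ptc-miRn35	UUGCCGACCCCACCCAUGCCAA	1127(309)	scaffold_10:12814698:12814812:-	3'	115	-49	D
Ptc-miRn36	UGGAUGAUCAUGUUGGCAACC	1614(364)	scaffold_4:6132662:6132818:+	3'	157	-60.3	BE
Ptc-miRn37	UGUGAUAAUGGAGGCUAUGGU	88(1)	scaffold_1:5941972:5942066:+	3'	95	-75.8	E
Ptc-miRn38	UAAUAAAAUCUCGACUAUUAU	249(4)	scaffold_11:535912:536007:-	5'	96	-44	
Ptc-miRn39	UGGACUCCUUUGGGGAGAUGG	216(2)	scaffold_15:12480557:12480647:+	3'	91	-41.1	BE
Ptc-miRn40	UCGAAUUUGGGCUUGAGAUUG	50787(2158)	scaffold_3:9383285:9383395:+	3'	111	-45.4	ABE
Ptc-miRn41	GGAAACCUUUUGUGGGGGUUU	491(9)	scaffold_15:12329506:12329600:-	3'	95	-44.7	DE
Ptc-miRn42	GGCAUGAGGUGUUUGGCAAGA	1721(1155)	scaffold_5:11901572:11901665:-	5'	94	-38.9	A
Ptc-miRn43	GAUGGGAUUUUUCGGGAAGUG	41(13)	scaffold_10:17756662:17756763:+	3'	102	-52.3	
Ptc-miRn44	GUUUUCCCUGAAUCACUCCCA	15(7)	scaffold_5:21920822:21920920:-	5'	99	-55.8	
Ptc-miRn45a	UGGGUGGGAGGUGUGGUAGCU	8(1)	scaffold_5:9237322:9237483:-	5'	162	-79.9	
Ptc-miRn45b	UGGGUGGGAGGUGUGGUAGCU	8(1)	scaffold_724:8193:8213:+	5'	166	-78.7	
Ptc-miRn46	ACAUGUGCUGGGUAGGAGGAA	21(4)	scaffold_6:9390506:9390758:-	3'	253	-86.8	
Ptc-miRn47	AGUGGCAUUGGAGGUAUCCC	297(18)	scaffold_1:22901250:22901371:-	3'	122	-34.7	D
Ptc-miRn48	UCUCAAGCCCAAAUUCGAUC	8(2)	scaffold_3:9383296:9383382:-	5'	87	-35	B
Ptc-miRn49	CAAGGAGUAAUUAGUGACAUC	974(1)	scaffold_9:7737213:7737443:+	5'	231	-63.3	
Ptc-miRn50	UGAUAUGUGGCAUUCAAUCGA	2880(8)	scaffold_3:14915775:14915873:+	3'	99	-77.1	E
Ptc-miRn51a	GCCGAGCUCGGGGAUUGCG	84645(465)	scaffold_17:2344664:2344909:+	3'	246	-141.5	
Ptc-miRn51b	GCCGAGCUCGGGGAUUGCG	84645(465)	scaffold_17:2357226:2357471:+	3'	246	-143	
Ptc-miRn51c	GCCGAGCUCGGGGAUUGCG	84645(465)	scaffold_17:2307047:2307292:+	3'	246	-137.4	
Ptc-miRn51d	GCCGAGCUCGGGGAUUGCG	84645(465)	scaffold_17:2279166:2279411:+	3'	246	-137.6	
Ptc-miRn51e	GCCGAGCUCGGGGAUUGCG	84645(465)	scaffold_17:2268545:2268790:+	3'	246	-139.3	
Ptc-miRn52	GGGGGUUGCUGUCAAGCAUAA	61(19)	scaffold_18:2804678:2804833:+	3'	156	-74.6	B
Ptc-miRn53	UAAAUCAAGCCCGGUACUUUU	10(2)	scaffold_11:15209261:15209374:-	5'	114	-42.6	
Ptc-miRn54a	UUCAUUCCUCUUCCUAAAAUGG	1827(506)	scaffold_15:8556706:8556831:+	5'	126	-61	ABCE
Ptc-miRn54b	UUCAUUCCUCUUCCUAAAAUGG	1827(500)	scaffold_12:7706162:7706287:-	5'	126	-50.9	ABCDE
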