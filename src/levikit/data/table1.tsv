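name	group	length	cysteines	ss	tr	production	sol_37	sol_15	vlp_em	morphology	diameter_nm	tm_c	reference
MS2	MS2	129			++	+++	+++	n.d.	+++	T = 3	28	70	1
Qβ	MS2	132	74, 80	56	++	+++	+++	n.d.	+++	T = 3	30	90	1
PRR1	MS2	131			++	+++	+++	n.d.	+++	T = 3	n.d.	75	1
PP7	MS2	127	67, 72	56	++	+++	+++	n.d.	+++	T = 3	27	90	1
AP205	AP205	130	64, 68	56		+++	+++	n.d.	+++	T = 3, T = 1	28	75	1
Cb5	Cb5	122				+++	+++	n.d.	+++	T = 3	28	70	1
AIN000	MS2	131				+++	-	+	+++	T = 3	n.d.	45	0
AIN002	MS2	132				+++	-	+	+++	T = 3	n.d.	55	0
AIN003	MS2	140				+++	-	+	+++	T = 3	28	55	0
AIN010	MS2	125				+/-	+	n.d.	-	n/a	n/a	n/a	0
AVE017	MS2	129			+	+++	+++	n.d.	++	T = 3	26	65	0
AVE019	MS2	123			+	+++	+++	n.d.	+	T = 3	27	50	0
AVE021	MS2	123				+++	+++	n.d.	++	T = 3	30	60	0
Beihai16	MS2	128			+	+++	+++	n.d.	-	n/a	n/a	n/a	0
Beihai17	MS2	129				+++	+++	n.d.	++	T = 3, T = 1	26	55	0
Beihai18	MS2	131				+++	+++	n.d.	+	T = 3	29	50	0
Beihai19	MS2	134			+	+++	+++	n.d.	+	T = 3	28	55	0
Beihai21	MS2	126				+++	+++	n.d.	+	T = 3	n.d.	40	0
Beihai23	MS2	130				+	+++	n.d.	+	T = 3	28	35	0
Beihai26	MS2	123			+	+++	+++	n.d.	+	T = 3	n.d.	50	0
Beihai27	MS2	122				+++	+++	n.d.	-	n/a	n/a	n/a	0
Beihai28	MS2	132			+	+++	+++	n.d.	++	T = 3	30	65	0
Beihai30	MS2	149				++	+++	n.d.	++	T = 3	n.d.	65	0
Beihai32	MS2	130				+++	+++	n.d.	++	T = 3	31	70	0
Beihai33	MS2	126			+	+++	+++	n.d.	+++	T = 3	28	n.d.	0
Beihai34	MS2	121				+++	+++	n.d.	+	T = 3	25	50	0
EMS014	MS2	156				++	+++	n.d.	+	T = 3	n.d.	n.d.	0
EOC000	MS2	129			+	+++	-	+	+++	T = 3	n.d.	n.d.	0
EOC005	MS2	159				+++	-	+	++	T = 3	n.d.	60	0
ESE005	MS2	149			+	+++	-	-	n.d.	n/a	n/a	n/a	0
ESE006	MS2	129			+	+++	-	++	+++	T = 3	n.d.	n.d.	0
ESE007	MS2	137	93, 115	N		+++	-	++	+++	T = 3	30	90	0
ESE009	MS2	130				+++	-	+	-	n/a	n/a	n/a	0
ESE010	MS2	132				+	+++	n.d.	-	n/a	n/a	n/a	0
ESE012	MS2	143				++	+++	n.d.	+	T = 3	n.d.	n.d.	0
ESE019	MS2	150				+++	-	+	+++	T = 3	32	50	0
ESE021	MS2	150			+	+++	-	+	+	T = 3	n.d.	50	0
ESE024	MS2	149				+++	-	+	++	T = 3	29	50	0
ESE025	MS2	152				+++	-	++	+++	T = 3	36	40	0
ESE029	MS2	132				+++	+++	n.d.	+++	T = 3	22	70	0
ESE030	MS2	142				+++	-	++	+++	T = 3	n.d.	35	0
ESE037	MS2	140			+	+++	-	++	+++	T = 3	n.d.	70	0
ESE046	MS2	137				+++	-	++	+++	T = 3	31	36	0
ESE058	MS2	146			+	+++	-	++	+++	T = 3	n.d.	55	0
ESO010	MS2	149			+	+++	-	+	-	n/a	n/a	n/a	0
Hubei2	MS2	124				+	+++	n.d.	-	n/a	n/a	n/a	0
Hubei3	MS2	128				+++	-	+	++	T = 3	n.d.	60	0
Hubei6	MS2	125				++	+++	n.d.	++	T = 3	24	60	0
Hubei8	MS2	137				+++	-	+	++	T = 3	26	40	0
Hubei10	MS2	129	76, 77	56		+++	+++	n.d.	++	T = 3	30	70	0
Hubei14	MS2	117			+	+++	+++	n.d.	+++	T = 3	28	70	0
NFYT01000214	MS2	135	78, 79, 95			++	+++	n.d.	++	T = 3	42	65	0
NFZC01009824	MS2	122	68, 70	n.d.		+	+++	n.d.	++	T = 3	n.d.	n.d.	0
Shahe3	MS2	136			+	+++	-	+	++	T = 3	29	50	0
Wenling2	MS2	128			+	+++	+++	n.d.	++	T = 3	28	70	0
Wenling3	MS2	126				+++	+++	n.d.	+	T = 3	26	60	0
Wenzhou4	MS2	146			+	+++	-	++	+++	T = 3	30	50	0
AVE004	AVE015	159	107, 108	n.d.	+	+++	+++	n.d.	+	T = 3	n.d.	n.d.	0
AVE006	AVE015	180				++	+++	n.d.	+	T = 3	n.d.	n.d.	0
AVE007	AVE015	156	46, 134	N		++	+++	n.d.	++	T = 3, T = 1	30	n.d.	0
AVE022	AVE015	158	59, 136			++	+++	n.d.	-	n/a	n/a	n/a	0
AVE024	AVE015	156	39, 58	N		+++	+++	n.d.	+	T = 3	n.d.	n.d.	0
AVE039	AVE015	158	56, 89, 130	N		+++	+++	n.d.	++	T = 3	n.d.	60	0
GALT01000492	AVE015	165	103, 104, 105	56		++	+++	n.d.	+++	Heterogenous	48	70	0
GALT01093879	AVE015	163	101, 102, 103	56		++	+++	n.d.	++	T = 3	30	75	0
AVE000	AVE015	167	61, 98, 99	N		+++	-	+++	+++	T = 4?	38	n.d.	0
AVE005	AVE015	164	94, 112	N	+	+++	-	+	+++	T = 3	40	70	0
AVE015	AVE015	167			+	+++	-	+	+++	T = 3	n.d.	65	0
AVE016	AVE015	166	113, 158	N		+++	+++	n.d.	++	T = 3, some elongated	30	95	0
AVE018	AVE015	169	9, 43, 92	D	+	+++	+++	n.d.	+	T = 3	28	70	0
AVE020	AVE015	180	38, 146			++	+++	n.d.	-	n/a	n/a	n/a	0
AVE023	AVE015	177			+	+++	-	-	n.d.	n/a	n/a	n/a	0
Beihai12	AVE015	178			+	+++	+++	n.d.	-	n/a	n/a	n/a	0
GALQ01044112	AVE015	164	8, 59, 113	N		+++	+++	n.d.	++	T = 3	32	80	0
AVE002	AVE002	140				+	++	n.d.	+++	T = 3	31	65	0
GALQ01040378	AVE002	151				-	-	-	n.d.	n/a	n/a	n/a	0
Beihai13	ESE017	132				+++	-	+	++	T = 3	n.d.	n.d.	0
ESE017	ESE017	132				+	+++	n.d.	+	T = 3	27	70	0
GALQ01034907	ESE017	131				+	++	n.d.	+	T = 3	27	60	0
Beihai20	AP205	117				++	+++	n.d.	-	n/a	n/a	n/a	0
EMS002	Cb5	123	64, 68		+	+++	-	++	-	n/a	n/a	n/a	0
EMS011	Cb5	123	64, 68	56		+++	-	+	+++	T = 3	33	55	0
EMS017	Cb5	123	64, 68			-	-	n.d.	n.d.	n/a	n/a	n/a	0
ESE016	Cb5	123				++	+++	n.d.	-	n/a	n/a	n/a	0
ESO001	Cb5	124			+	+++	-	+	+++	T = 3	40	n.d.	0
Beihai3	Cb5	119				+++	+/-	n.d.	+	T = 3	24	60	0
Beihai6	Cb5	119			+	+++	+++	n.d.	-	n/a	n/a	n/a	0
MB	Cb5	127				++	-	++	-	n/a	n/a	n/a	0
Beihai1	Cb5	116				+	+++	n.d.	+	T = 3	n.d.	n.d.	0
EMS007	Cb5	116			+	+++	+/-	n.d.	-	n/a	n/a	n/a	0
ESE008	Cb5	138			+	+++	-	+++	-	n/a	n/a	n/a	0
ESE015	Cb5	119				+	+++	n.d.	+	T = 3	31	55	0
ESE022	Cb5	116				++	-	++	-	n/a	n/a	n/a	0
ESE026	Cb5	119			+	+++	+++	n.d.	+	T = 3	n.d.	50	0
ESO000	Cb5	115			+	+++	-	++	-	n/a	n/a	n/a	0
Wenzhou2	Cb5	122				+++	+/-	n.d.	++	T = 3	26	60	0
Beihai9	Cb5	123				++	+++	n.d.	++	T = 3	29	50	0
Wenling1	Cb5	116				+	+++	n.d.	-	n/a	n/a	n/a	0
Changjiang1	Cb5	112				++	+++	n.d.	+	T = 3	n.d.	n.d.	0
EMS005	Cb5	112				+++	+++	n.d.	-	n/a	n/a	n/a	0
Wenzhou1	Cb5	113				++	+++	n.d.	++		n.d.	n.d.	0
EMM000	ESE020	155			+	+++	-	+	++	T = 3	23	50	0
EMS001	ESE020	154				+	+++	n.d.	++	T = 3	n.d.	65	0
ESE020	ESE020	153			+	+++	+++	n.d.	+	T = 3	36	65	0
ESE041	ESE020	155			+	+++	-	+	+++	T = 3	34	50	0
AC	AC	115				+++	-	++	+++	T = 3	n.d.	50	0
NFYT01000391	AC	123	66, 67, 75	N		+	+++	n.d.	++	T = 1	18	75	0
NFZC01007443	AC	119	64, 66	5		++	+++	n.d.	++	T = 1	19	60	0
EMS000	EMS000	105	45, 48			+	+++	n.d.	-	n/a	n/a	n/a	0
EMS003	EMS000	106				+++	-	+	-	n/a	n/a	n/a	0
AVE001	AVE001	202	82, 83, 84		+	+++	-	-	n.d.	n/a	n/a	n/a	0
AVE003	AVE001	183	88, 90, 176		+	+++	-	-	n.d.	n/a	n/a	n/a	0
Beihai14	Beihai14	208			+	+++	-	+	+++	T = 3	31	85	0
ESE001	ESE001	118	61, 66	56		+++	+/-	n.d.	++	T = 3	30	75	0
ESO003	ESO003	113				++	+++	n.d.	++	T = 3	29	60	0
AIN001	AIN001	155				+++	-	-	n.d.	n/a	n/a	n/a	0
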