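biotype	country	locality	lat	long	aoc	noi	nomka	noge	noagm
EE	Hungary	Szodrakosz Cr.	47°43'58.8"N	19°07'58.8"E	-	1	5	-	-
EE	Poland	Budkowiczanka R.	50°50'50.1"N	18°11'07.1"E	-	1*	-	-	-
TT	Germany	Haaren Cr.	53°04'58.8"N	7°49'58.8"E	-	2* + 1	4	-	-
NN	Romania	Danube R.	44°04'47.9"N	26°43'51.2"E	-	2*	-	-	-
NN	Romania	Sinoe at Histria	44°37'58.8"N	28°52'58.8"E	-	1	4	-	-
ET	Czech Rep.	Laboratory F1	50°24'37.6"N	14°27'16.9"E	F1 generation	1	9	1	4
ET	Poland	Dolna Barycz R.	51°36'59.1"N	16°30'49.1"E	Holocene	4	27	2	4
EN	Bulgaria	Jantra R.	43°09'58.0"N	25°55'53.8"E	hybrid clade I	2	22	1	1
EN	Romania	Danube R.	44°04'47.9"N	26°43'51.2"E	hybrid clade I	3	15	2	9
EET	Germany	Neisse R.	51°51'28.8"N	14°36'34.9"E	Holocene	1	12	1	8
EET	Poland	Polska Woda R.	51°31'17.0"N	17°30'07.0"E	Holocene	3	16	-	-
EET	Poland	Dolna Barycz R.	51°36'59.1"N	16°30'49.1"E	Holocene	2	5	1	2
EET	Czech Rep.	Pšovka Cr.	50°22'11.8"N	14°33'06.8"E	Holocene	1	2	-	-
ETT	Germany	Issel R.	51°51'00.0"N	06°15'00.0"E	Holocene	2	13	2	3
ETT	Germany	Ilmenau R.	53°22'34.0"N	10°14'36.5"E	Holocene	1	2	-	-
ETT	Czech Rep.	Laboratory B1	50°24'37.6"N	14°27'16.9"E	B1 generation	3	17	2	10
EEN	Bulgaria	Vit R.	43°15'47.0"N	24°19'30.1"E	hybrid clade I	2	56	2	6
EEN	Poland	Polska Woda R.	51°31'17.0"N	17°30'07.0"E	hybrid clade I	1	7	1	1
EEN	Romania	Barlat R.	46°40'23.8"N	27°40'07.5"E	Holocene	3	6	-	-
EEN	Romania	Comana R.	44°10'07.1"N	26°08'54.9"E	hybrid clade I	1	2	-	-
EEN	Romania	Adjud R.	46°04'21.0"N	27°12'32.2"E	Holocene	1	2	-	-
EEN	Slovakia	Cierna voda R.	48°36'27.0"N	21°59'34.1"E	hybrid clade I	8	51	5	17
ENN	Romania	Danube R.	44°04'47.9"N	26°43'51.2"E	Holocene	10	35	3	12
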