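study_id	author	year	ethnicity	disease	endpoints	tt_case	ct_case	cc_case	tt_ctrl	ct_ctrl	cc_ctrl	dose_tt_n	dose_tt_mean	dose_tt_sd	dose_ct_n	dose_ct_mean	dose_ct_sd	dose_cc_n	dose_cc_mean	dose_cc_sd	dose_tcarrier_n	dose_tcarrier_mean	dose_tcarrier_sd
Yang-2014	Suk-Kyun Yang	2014	Korean	IBD	myelotoxicity	14	133	199	0	43	589												
Kakuta-2015	Y Kakuta	2015	Japanese	IBD	myelotoxicity	5	10	19	0	13	88												
Asada-2016	Ayumi Asada	2016	Japanese	IBD	myelotoxicity	2	18	25	0	14	102												
Zhu-2016	X. Zhu	2016	Chinese Han	IBD	myelotoxicity	4	36	25	0	17	171												
Tanaka-2015	Yoichi Tanaka	2015	Japanese	ALL	myelotoxicity	5	13	20	1	5	48												
Chiengthong-2016	Kanhatai Chiengthong	2016	Thai	ALL	myelotoxicity	1	9	18	1	1	52												
Suzuki-2016	Hisato Suzuki	2016	Japanese	ALL	myelotoxicity	0	10	36	0	0	5												
Yang-2014-dose	Suk-Kyun Yang	2014	Korean	IBD	dose							14	2.335	0.485	176	3.697	2.145	788	4.472	2.436			
Kakuta-2015-dose	Y Kakuta	2015	Japanese	IBD	dose										23	1.613	0.891	107	2.915	1.203			
Asada-2016-dose	Ayumi Asada	2016	Japanese	IBD	dose							2	2.12		32	2.26	1.13	127	2.43	1.27			
Shah-2016	Swarup A. V. Shah	2016	Indian	IBD	dose													60	2.858	0.566	9	2.066	0.566
YangJJ-2015-EastAsian	Jun J. Yang	2015	East Asian	ALL	dose							1	10.125		10	35.55	11.25	50	59.85	17.85			
YangJJ-2015-Hispanic	Jun J. Yang	2015	Hispanic	ALL	dose							1	2.175		16	52.425	13.4	205	65.85	16.65			
YangJJ-2015-Other	Jun J. Yang	2015	Other	ALL	dose										5	59.475	13.95	375	64.35	17.55			
Liang-2015	D-C Liang	2015	Taiwan Chinese	ALL	dose							2	18.8	7.4	70	61.4	23.4	238	88.2	30.6			
Chiengthong-2016-dose	Kanhatai Chiengthong	2016	Thai	ALL	dose													70	86.542	9.525	12	54.608	8.719
Moriyama-2016-Guatemala	Takaya Moriyama	2016	Guatemala	ALL	dose							1	8.944		18	54.954	34.516	162	69.638	30.261			
Moriyama-2016-Singapore	Takaya Moriyama	2016	Singaporean	ALL	dose							1	5.522		17	65.894	25.765	65	91.354	27.674			
Moriyama-2016-Japan	Takaya Moriyama	2016	Japanese	ALL	dose							1	5.013		9	69.95	28.912	22	99.674	34.231			
Suzuki-2016-dose	Hisato Suzuki	2016	Japanese	ALL	dose										10	59.946	16.405	41	65.647	23.887			
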