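# Reference serum-extract ion table for nusinersen metabolites (published
# LC-ESI-Q-TOF study of pediatric SMA patients treated with Spinraza).
# One row per reported species: observed ions (mz1 always present; mz2 blank for
# single-charge-state species), charge magnitudes (negative mode), retention time,
# the m/z values the original isotope-distribution tool reported, the deconvoluted
# neutral mass and the predicted mass as printed, the reported candidate sequence
# strings ("|"-separated alternatives; "*" = phosphorothioate, "MoeR" = abasic
# MOE-ribose) and the reported shortmer labels.
# note flags: ok = internally consistent; deconv_erratum = printed deconvoluted
# mass is inconsistent with the row's own ions (excluded from deconvolution
# checks); the two rows sharing label 5'N-11+3'N-4 with different masses are a
# probable label erratum in the source and are transcribed verbatim.
mz1	z1	mz2	z2	rt	iso_mz1	iso_mz2	deconvoluted_mass	predicted_mass	sequences	metabolite	note
855.30	1			8.81	855.30		856.30	855	G*G*	5'N-16	ok
969.35	1			8.98	969.92		970.35	971	mU*mC*MoeR|mC*mU*MoeR	3'N-16 or 5'N-6+3'N-10 or 5'N-3+3'N-13 or 5'N-14+3'N-2	ok
1127.42	1			9.21	1127.35		1128.42	1128	G*mU*mC|mU*G*mC	5'N-14+3'N-1 or 5'N-12+3'N-3	ok
731.31	2	1463.62	1	9.44	731.35	1463.73	1464.62	1464	*mU*mU*mU*MoeR	5'N-4+3'N-11	ok
653.26	2	1307.52	1	9.46	653.21	1307.43	1308.52	1308	*A*A*mU*|*mU*A*A*	5'N-10+3'N-5 or 5'N-9+3'N-6	ok
1105.47	1			9.48	1105.37		1106.47	1104	mU*mU*mU	5'N-4+3'N-11	ok
595.74	2	1192.50	1	9.51	593.48	1185.97	1193.49	1194	mC*mU*mU*|mU*mU*mC*	5'N-3+3'N-12 or 5'N-5+3'N-10	ok
673.80	2	1348.60	1	9.54	673.84	1348.70	1349.60	1349	MoeR*mU*A*MoeR*|MoeR*A*mU*MoeR*	5'N-11+3'N-5 or 5'N-8+3'N-8 or 5'N-9+3'N-7	ok
601.77	2	1204.55	1	9.63	602.07	1205.15	1205.55	1205	mC*A*mU*|mU*mC*A*|A*mC*mU*	5'N-7+3'N-8 or 3'N-15 or 5'N-2+3'N-13	ok
806.81	2	1614.62	1	9.97	806.85	1614.71	1615.62	1614	A*mU*A*A*	5'N-8+3'N-6	ok
771.29	2	1543.59	1	10.00	771.23	1543.48	1544.59	1543	G*G*mU*mC	3'N-14	ok
728.76	2	1458.52	1	10.04	728.72	1458.45	1459.52	1458	A*mC*mU*MoeR*|mU*mC*A*MoeR*|mC*A*mU*MoeR*	5'N-2+3'N-13 or 5'N-6+3'N-9 or 5'N-7+3'N-8	ok
661.24	2	1323.50	1	10.28	661.29	1323.58	1324.49	1325	*A*mU*G*	5'N-11+3'N-4	ok
617.73	2	1236.46	1	10.45	617.59	1236.39	1237.46	1233	A*mU*G*	5'N-11+3'N-4	ok
748.79	2	1498.58	1	10.45	748.73	1498.47	1499.47	1499	mU*mC*A*mC	3'N-14 or 5'N-1+3'N-13	deconv_erratum
696.76	2	1394.54	1	10.60	696.70	1394.41	1395.41	1395	G*mU*mC*MoeR|mU*G*mC*MoeR	5'N-15+3'N-1 or 5'N-12+3'N-3	deconv_erratum
697.25	2	1395.51	1	10.83	697.30	1395.41	1396.50	1396		unidentified	ok
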