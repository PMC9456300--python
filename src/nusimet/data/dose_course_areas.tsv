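# Reference EIC peak-area dose-course table for two patients (P1, P2) treated
# with intrathecal nusinersen. Columns: ion m/z, reported metabolite label, then
# per-sample dose columns (B/A = before/after, I..IV = dose number). "-" means
# not detected. Thousands separators from the printed source were removed.
# The P1_AIIID value 5416 for ion 1307.52 is anomalous versus its neighbours and
# is transcribed verbatim (probable erratum in the source).
# P2 was only sampled at BID, AID and BIID.
mz	metabolite	P1_BID	P1_AID	P1_BIID	P1_AIID	P1_BIIID	P1_AIIID	P1_BIVD	P1_AIVD	P2_BID	P2_AID	P2_BIID
855.30	5'N-16	-	-	22292	41846	60277	91142	84509	99599	-	27448	12001
969.35	3'N-16 or 5'N-6+3'N-10 or 5'N-3+3'N-13 or 5'N-14+3'N-2	-	-	60944	87659	100005	138235	98860	107452	-	35669	19241
1127.42	5'N-14+3'N-1 or 5'N-12+3'N-3	-	-	20356	47092	28043	65380	18313	40026	-	-	-
731.31	5'N-4+3'N-11	-	-	375922	684992	235724	889988	367031	320948	-	111877	81756
1463.62	5'N-4+3'N-11	-	-	386093	709428	288171	923407	189957	976055	-	30627	19004
653.26	5'N-10+3'N-5 or 5'N-9+3'N-6	-	-	479340	549774	509698	650947	484355	513908	-	100994	61892
1307.52	5'N-10+3'N-5 or 5'N-9+3'N-6	-	-	439999	551092	524610	5416	371283	499875	-	92650	55528
1105.47	5'N-4+3'N-11	-	-	38654	49387	90130	143078	113883	438601	-	30845	20516
595.74	5'N-3+3'N-12 or 5'N-5+3'N-10	-	-	43878	76738	83663	129864	100645	123984	-	17933	11278
1192.50	5'N-3+3'N-12 or 5'N-5+3'N-10	-	-	117383	183000	214185	318363	224654	270008	-	46995	32846
673.80	5'N-11+3'N-5 or 5'N-8+3'N-8 or 5'N-9+3'N-7	-	-	19746	24874	20503	45787	16843	24777	-	-	-
1348.60	5'N-11+3'N-5 or 5'N-8+3'N-8 or 5'N-9+3'N-7	-	-	26803	35091	37870	96701	38993	70664	-	-	-
601.77	5'N-7+3'N-8 or 3'N-15 or 5'N-2+3'N-13	-	-	78121	96364	114024	149239	98453	116630	-	26008	15541
1204.55	5'N-7+3'N-8 or 3'N-15 or 5'N-2+3'N-13	-	-	290662	370111	407015	617843	296511	454855	-	51278	27922
771.29	3'N-14	-	-	119743	150487	161380	192834	193251	235326	-	250180	257313
1543.59	3'N-14	-	-	22891	29055	30772	37718	51847	42685	-	51660	51872
728.76	5'N-2+3'N-13 or 5'N-6+3'N-9 or 5'N-7+3'N-8	-	-	99638	134029	163227	241621	276904	318706	-	190819	164560
1458.52	5'N-2+3'N-13 or 5'N-6+3'N-9 or 5'N-7+3'N-8	-	-	35011	49366	53134	79228	91123	97483	-	68820	55182
806.81	5'N-8+3'N-6	-	-	246981	350000	408377	711294	316112	340207	-	219256	169060
1614.62	5'N-8+3'N-6	-	-	107999	163227	218298	116891	46764	57868	-	33602	23482
661.24	5'N-11+3'N-4	-	-	91447	120778	129391	145323	167028	166360	-	140036	108420
1323.50	5'N-11+3'N-4	-	-	156883	200827	264920	287088	253539	284406	-	270916	231482
617.73	5'N-11+3'N-4	-	-	141226	196889	188981	445875	441159	707505	-	636703	547665
1236.46	5'N-11+3'N-4	-	-	504634	730087	634256	1365200	1488668	1749378	-	2076167	1958401
748.79	3'N-14 or 5'N-1+3'N-13	-	-	10007	14763	16877	24332	19870	21998	-	9643	12855
1498.58	3'N-14 or 5'N-1+3'N-13	-	-	13928	18995	26743	36909	31651	34037	-	10273	14334
696.76	5'N-15+3'N-1 or 5'N-12+3'N-3	-	-	640294	911653	1149054	1203453	903786	1063517	-	202241	184736
1394.54	5'N-15+3'N-1 or 5'N-12+3'N-3	-	-	776380	1069312	1382465	1590716	900278	1292842	-	242374	227235
697.25	unidentified	-	-	369944	523095	634515	899517	388974	483546	-	269885	176447
1395.51	unidentified	-	-	285092	409661	454274	711694	232607	357814	-	226691	132025
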