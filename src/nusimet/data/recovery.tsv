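# Reference recovery percentages (mean +/- sd across replicates) of selected
# nusinersen metabolites after second-stage cleanup of liquid-liquid extracts,
# relative to the EIC peak areas of the LLE extracts. Methods: SPE (solid-phase
# extraction), MEPS (microextraction by packed sorbent, SDVB or C18 sorbent)
# and MNPs (magnetic nanoparticles).
metabolite	mz	SPE	SPE_sd	MEPS_SDVB	MEPS_SDVB_sd	MEPS_C18	MEPS_C18_sd	MNPs	MNPs_sd
5'N-10+3'N-5 or 5'N-9+3'N-6	653.26	91	2	85	1	78	2	66	5
5'N-10+3'N-5 or 5'N-9+3'N-6	1307.52	92	1	87	2	80	1	63	2
5'N-11+3'N-4	661.24	93	3	84	2	77	1	66	3
5'N-11+3'N-4	1323.50	94	4	84	2	76	1	63	4
5'N-11+3'N-4	617.73	98	3	86	1	80	2	65	4
5'N-11+3'N-4	1236.46	97	4	83	2	78	3	65	4
5'N-15+3'N-1 or 5'N-12+3'N-3	696.76	96	4	80	1	79	1	63	5
5'N-15+3'N-1 or 5'N-12+3'N-3	1394.54	96	3	81	1	78	1	68	3
3'N-14	771.29	90	4	86	1	76	2	71	4
3'N-14	1543.59	91	5	86	2	75	2	69	3
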