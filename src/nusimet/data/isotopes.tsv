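# Stable-isotope masses (Da) and relative abundances for the elements of
# phosphorothioate MOE oligonucleotides (H, C, N, O, P, S).
# Values: CIAAW / NIST "Atomic Weights and Isotopic Compositions" compilation.
# Per element: rows ordered by increasing isotope mass; abundances sum to 1.
element	mass	abundance
H	1.00782503207	0.999885
H	2.01410177785	0.000115
C	12.0	0.9893
C	13.00335483507	0.0107
N	14.00307400443	0.99636
N	15.00010889888	0.00364
O	15.99491461957	0.99757
O	16.99913175650	0.00038
O	17.99915961286	0.00205
P	30.97376199842	1.0
S	31.97207117440	0.9499
S	32.97145890980	0.0075
S	33.96786700400	0.0425
S	35.96708071000	0.0001
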