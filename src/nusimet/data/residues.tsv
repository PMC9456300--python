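# Residue registry for 2'-O-methoxyethyl (MOE) oligonucleotides.
# base_formula is the free nucleobase; the nucleoside formula is derived as
# base + ribose (C5H10O5) + MOE substitution (C3H6O) - H2O (glycosidic bond).
code	base_name	base_formula
mU	5-methyluracil	C5H6N2O2
mC	5-methylcytosine	C5H7N3O
A	adenine	C5H5N5
G	guanine	C5H5N5O
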