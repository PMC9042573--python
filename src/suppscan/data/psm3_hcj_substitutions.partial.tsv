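# Partial list: only substitutions whose wild-type and mutant residues are
# both named in the published text; hit counts unknown (omitted).
position	wt_aa	mut_aa
106	K	R
127	S	P
127	S	R
127	S	K
127	S	E
128	A	R
128	A	K
128	A	E
129	G	R
129	G	K
129	G	E
164	G	D
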