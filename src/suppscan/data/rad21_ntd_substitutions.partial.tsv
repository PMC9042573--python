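# Partial list: only substitutions whose wild-type and mutant residues are
# both named in the published text; hit counts unknown (omitted).
position	wt_aa	mut_aa
42	H	P
53	A	V
59	Q	R
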