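PROJECT
	NAME	toyglyc_energy

// Energy/redox variant of the toy network: same carbon skeleton and reaction
// ids plus cofactor stoichiometry (ATP, NADH, NADPH carry no carbon), an
// oxidative-phosphorylation lump (resp) and an ATP maintenance drain (atpm).
// Used for FBA and cofactor bookkeeping; labelling tests use toyglyc.ftbl.

NETWORK
	upt	GLYC#abc + ATP -> T#abc
	cond	T#abc + T#def -> H#abcdef
	cleave	H#abcdef <-> T#abc + T#def
	scramble	H#abcdef -> P#ab + T#cde + CO2#f + 2 NADPH
	t2p	T#abc -> PYR#abc + ATP + NADH
	pdc	PYR#abc -> ACD#bc + CO2#a
	ace_out	ACD#ab -> ACE#ab
	pyr_out	PYR -> BIO
	p_out	P -> BIO
	bio	T + 2 ATP + 0.5 NADPH -> BIO
	resp	NADH -> 2 ATP
	atpm	ATP -> SINK

LABEL_INPUT
	GLYC

MEASUREMENTS
	RATE	upt
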