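PROJECT
	NAME	toyglyc

// Minimal glycerol-like labelling network: uptake, condensation, reversible
// cleavage, a PPP-like scrambling split, decarboxylation, and lumped sinks.
// The scramble returns a 3-carbon unit straddling both halves of H so that
// positional tracer mixtures carry information about the split ratio.

NETWORK
	upt	GLYC#abc -> T#abc
	cond	T#abc + T#def -> H#abcdef
	cleave	H#abcdef <-> T#abc + T#def
	scramble	H#abcdef -> P#ab + T#cde + CO2#f
	t2p	T#abc -> PYR#abc
	pdc	PYR#abc -> ACD#bc + CO2#a
	ace_out	ACD#ab -> ACE#ab
	pyr_out	PYR -> BIO
	p_out	P -> BIO
	bio	T -> BIO

LABEL_INPUT
	GLYC

FLUXES
	free	scramble
	free	cond
	bounds	upt	0	100

MEASUREMENTS
	MID	PYR	C3H4O3
	MID	ACD	C2H4O
	RATE	upt
	RATE	ace_out
	RATE	pyr_out
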