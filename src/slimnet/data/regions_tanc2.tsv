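accession	region	start	end
Q9HCD6	N-term	1	119
Q9HCD6	NTPase	120	900
Q9HCD6	ANK	901	1250
Q9HCD6	TPR	1300	1450
Q9HCD6	C-term	1451	1990
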