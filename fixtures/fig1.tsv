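id	substrates	products	reversible	boundary
t1		3*p1 + 2*p2	irr	input
t2	2*p2	p1	irr	internal
t3	p1		irr	output
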