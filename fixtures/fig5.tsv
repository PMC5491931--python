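id	substrates	products	reversible	boundary
t1		p1 + p2	irr	input
t2	p1	p2	irr	internal
t3	p2	p1	irr	internal
t4	p1		irr	output
t5	p2		irr	output
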