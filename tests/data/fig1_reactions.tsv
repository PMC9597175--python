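id	equation	lb	ub	gpr	confidence
r1	A[c] -> B[c]	0	10	G1	other
r2	B[c] -> C[c]	0	10	G2 or G3	other
r3	B[c] -> D[c]	0	10	G2 or G3 or (G4 and G5)	other
r4	C[c] + D[c] -> E[c]	0	10		other
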