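marker	forward_seq	forward_tm_c	reverse_seq	reverse_tm_c	product_bp
adf225	CCATGCCCTGTACATTTGCG	59.89	CCGTGAACATGGAGGGGTTT	60.25	162
adf340	TTAACGGCCCTAACACCAGG	59.67	GGTTTAGGGCGGCTCTGATT	60.10	251
adf318	CTAGAAGACGTGGTGGCCATG	60.0	TATGTCAGGGTGATCAAACTCTTCA	59.52	66
adf431	CGAGCCTCCATTGTGCCTT	59.8	TCCAGAATGAAGTCCTGGCCT	59.1	178
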