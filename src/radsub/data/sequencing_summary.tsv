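sample	location	sex	reads	base_pairs	mid	rad_tags	mean_depth	coverage	q20_pct	q30_pct
adC1	Zhejiang	female	66274208	9531810907	GCTAC	6507944	10.2	0.19	97.92	93.56
adC2	Zhejiang	female	139991345	20139630928	CCTCT	9766767	14.3	0.41	97.94	93.59
adC3	Shandong	female	155877412	22421346688	TAATC	10029072	15.54	0.44	97.93	93.58
adC8	Shandong	female	93172870	13367981397	GGCTAC	8583073	10.9	0.27	97.91	94.17
adX1	Zhejiang	male	127979232	18418604178	GCTTA	9167503	13.9	0.37	97.97	93.7
adX2	Zhejiang	male	204881740	29486474863	TCCAC	11078999	18.5	0.59	97.98	93.7
adX3	Shandong	male	66176492	9590086571	CTCC	6443154	10.2	0.20	97.93	93.56
adX8	Shandong	male	79719690	11421575816	ACCTCT	8038551	9.9	0.23	97.95	94.1
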