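site	raw_reads	quality_reads	otus_096	sso_rel_pct	sso_abs_pct	coverage_pct	otus_096_subsampled	inverse_simpson
GoM140	535	430	58	36	43	89	17	6
GoM13	751	487	47	47	36	92	16	4
GoM17	892	226	27	63	26	89	15	3
GoM4463	1419	154	44	55	36	74	27	9
GoM156	1078	803	87	32	47	91	21	4
GB4573	1255	989	93	15	49	94	17	7
GB4484	834	572	66	29	55	90	14	4
AMV760	837	134	21	48	43	89	12	3
AMV825	637	376	50	56	32	88	19	3
HR19	708	65	13	62	23	83	13	3
NZ315	2043	722	65	28	52	93	16	3
Tomm	1756	173	33	58	24	84	18	6
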