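length	30	32	35	38	41	44	48	51	54.5
66	21	56	74	87	97	100	ND	ND	ND
58	ND	4	8	42	80	89	ND	ND	ND
44	ND	2	3	13	40	59	75	ND	ND
37	ND	ND	1.5	4	11	19	45	80	ND
30	ND	ND	ND	ND	4	5	20	40	61
21	ND	ND	ND	ND	ND	2	4	7	15
19	ND	ND	ND	ND	ND	1	3	3	5
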