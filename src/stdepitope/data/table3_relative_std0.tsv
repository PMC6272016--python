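proton	WT-NADP+	WT-NAD+	PP3CT-NADP+	PP3CT-NAD+	Y303S-NADP+	Y303S-NAD+
A2	100	NA	100	100	NA	100
A8	15	NA	49	57	NA	17
A1'	46	NA	66	48	NA	34
N2	17	NA	50	31	NA	20
N4	38	NA	53	39	NA	44
N5	33	NA	52	NA	NA	42
N6	14	NA	76	41	NA	18
N1'	27	NA	54	34	NA	NA
N4'	20	NA	68	51	NA	26
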