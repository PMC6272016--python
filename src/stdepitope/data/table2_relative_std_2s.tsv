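proton	WT-NADP+	WT-NAD+	PP3CT-NADP+	PP3CT-NAD+	Y303S-NADP+	Y303S-NAD+
A2	100	100	100	100	100	100
A8	13	16	27	29	12	23
A1'	43	40	40	50	NA	NA
N2	17	NA	27	19	17	19
N4	43	NA	40	35	44	32
N5	30	NA	40	NA	35	27
N6	13	NA	26	19	15	21
N1'	17	NA	27	21	NA	NA
N4'	20	NA	40	33	NA	NA
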