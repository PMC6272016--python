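complex	a2_absolute_std_percent
WT-NADP+	30
WT-NAD+	10
PP3CT-NADP+	1.5
PP3CT-NAD+	2.6
Y303S-NADP+	7.4
Y303S-NAD+	6.2
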