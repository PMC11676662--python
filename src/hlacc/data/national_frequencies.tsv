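allele	frequency	frequency_unit
B*08	0.077	fraction
B*40	0.05	fraction
B*47	0.006	fraction
B*73	0.001	fraction
DRB1*16	0.096	fraction
A*11	0.093	fraction
DRB1*13	0.105	fraction
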