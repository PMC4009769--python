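# Approximate TAIR10 Arabidopsis thaliana region partition (0-based half-open).
# Pericentromere and centromere boundaries are rounded literature estimates,
# shipped for convenience; supply your own BED for precise stratification.
Chr1	0	11500000	arm
Chr1	11500000	14500000	pericentromere
Chr1	14500000	15500000	centromere
Chr1	15500000	17500000	pericentromere
Chr1	17500000	30427671	arm
Chr2	0	2300000	arm
Chr2	2300000	3300000	pericentromere
Chr2	3300000	4000000	centromere
Chr2	4000000	6500000	pericentromere
Chr2	6500000	19698289	arm
Chr3	0	11000000	arm
Chr3	11000000	13300000	pericentromere
Chr3	13300000	14700000	centromere
Chr3	14700000	17000000	pericentromere
Chr3	17000000	23459830	arm
Chr4	0	2500000	arm
Chr4	2500000	3700000	pericentromere
Chr4	3700000	4600000	centromere
Chr4	4600000	6500000	pericentromere
Chr4	6500000	18585056	arm
Chr5	0	10000000	arm
Chr5	10000000	11500000	pericentromere
Chr5	11500000	12500000	centromere
Chr5	12500000	15000000	pericentromere
Chr5	15000000	26975502	arm
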