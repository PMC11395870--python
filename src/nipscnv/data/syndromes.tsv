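# Packaged microdeletion-syndrome screening catalog (coordinates GRCh37,
# 0-based half-open). Curated from the public clinical CNV resources
# (ClinGen dosage-sensitivity map, DECIPHER syndrome list); this static
# table replaces any live database dependency.
#genome_build=GRCh37
name	chrom	start	end	expected_state	min_overlap
Williams-Beuren (7q11.23)	chr7	72700000	74100000	loss	0.5
DiGeorge (22q11.2)	chr22	18900000	21900000	loss	0.5
Prader-Willi/Angelman (15q11.2-q13)	chr15	23600000	28400000	loss	0.5
Cri-du-chat (5p15)	chr5	0	12500000	loss	0.5
1p36 deletion	chr1	0	5400000	loss	0.5
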