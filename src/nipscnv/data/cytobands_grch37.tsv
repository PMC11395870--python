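# Abridged GRCh37 cytoband table: only the chromosome-7 bands flanking the
# Williams-Beuren critical region are included; segments elsewhere fall back
# to the chr:start_end ISCN form. 0-based half-open coordinates.
chrom	start	end	band
chr7	61100000	72700000	q11.22
chr7	72700000	77900000	q11.23
chr7	77900000	86400000	q21.11
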