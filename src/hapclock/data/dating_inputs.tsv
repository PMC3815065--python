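# Published dating inputs for C11+D4 carriers in the 1000 Genomes panel:
# chromosome counts, total differences from the modal haplotype, and the
# resampling effective sample size per population sample.
population	n_chrom	total_diff	ess
Combined	1013	822	19
CEU	165	110	13
GBR	178	136	14
FIN	180	160	10
TSI	193	105	18
IBS	28	24	9
PUR+MXL+CLM	231	249	16
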