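# The 16 core-region SNPs used for haplotype definition (nicknames c1-c16).
# rs IDs and allele states are authoritative; POSITIONS ARE SYNTHETIC
# (evenly spaced placeholders inside block C) because per-SNP coordinates
# are not part of the published block/haplotype tables.
site_id	position	ancestral	derived	nickname	kind
rs1834640	48392000	G	A	c1	SNP
rs2675345	48396800	G	A	c2	SNP
rs2469592	48401600	G	A	c3	SNP
rs2470101	48406400	C	T	c4	SNP
rs938505	48411200	C	T	c5	SNP
rs2433354	48416000	T	C	c6	SNP
rs2459391	48420800	G	A	c7	SNP
rs2433356	48425600	A	G	c8	SNP
rs2675347	48430400	G	A	c9	SNP
rs2675348	48435200	G	A	c10	SNP
rs1426654	48440000	G	A	c11	SNP
rs2470102	48444800	G	A	c12	SNP
rs16960631	48449600	A	G	c13	SNP
rs2675349	48454400	G	A	c14	SNP
rs3817315	48459200	T	C	c15	SNP
rs7163587	48464000	T	C	c16	SNP
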