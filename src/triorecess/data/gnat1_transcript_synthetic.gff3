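##gff-version 3
# Synthetic single-transcript coding model of human GNAT1 (350 aa).
# Exon genomic boundaries are constructed, not the real NM_144499.2
# boundaries; the model preserves what the NMD analysis needs: 8 coding
# exons, CDS 1053 nt including the stop, last coding exon = c.851-c.1053.
3	triorecess	mRNA	50206001	50221053	.	+	.	ID=GNAT1-synthetic
3	triorecess	CDS	50206001	50206119	.	+	0	ID=cds1;Parent=GNAT1-synthetic
3	triorecess	CDS	50208120	50208254	.	+	1	ID=cds2;Parent=GNAT1-synthetic
3	triorecess	CDS	50210255	50210360	.	+	1	ID=cds3;Parent=GNAT1-synthetic
3	triorecess	CDS	50212361	50212487	.	+	0	ID=cds4;Parent=GNAT1-synthetic
3	triorecess	CDS	50214488	50214590	.	+	2	ID=cds5;Parent=GNAT1-synthetic
3	triorecess	CDS	50216591	50216706	.	+	1	ID=cds6;Parent=GNAT1-synthetic
3	triorecess	CDS	50218707	50218850	.	+	2	ID=cds7;Parent=GNAT1-synthetic
3	triorecess	CDS	50220851	50221053	.	+	2	ID=cds8;Parent=GNAT1-synthetic
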