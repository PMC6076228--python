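##fileformat=VCFv4.2
##source=mendiag validation fixture: 9 probands with 11 known causal mutations
##NOTE=Genomic coordinates are SYNTHETIC stand-ins; the source reports mutations in cDNA notation only (HGVSC carries that notation).
##contig=<ID=1>
##contig=<ID=12>
##contig=<ID=16>
##contig=<ID=17>
##contig=<ID=X>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Coding consequence">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of CNV">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=PROBAND,Number=1,Type=String,Description="Proband identifier">
##INFO=<ID=HGVSC,Number=1,Type=String,Description="cDNA-level notation as reported">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
1	179526000	.	A	C	.	PASS	GENE=NPHS2;CONSEQ=missense;PROBAND=P7;HGVSC=c.593A>C
1	179528000	.	G	A	.	PASS	GENE=NPHS2;CONSEQ=missense;PROBAND=P7;HGVSC=c.538G>A
12	102142000	.	C	T	.	PASS	GENE=GNPTAB;CONSEQ=nonsense;PROBAND=P3;HGVSC=c.1090C>T
12	102155000	.	C	T	.	PASS	GENE=GNPTAB;CONSEQ=nonsense;PROBAND=P3;HGVSC=c.2404C>T
16	2140000	.	C	G	.	PASS	GENE=PKD1;CONSEQ=missense;PROBAND=P5;HGVSC=c.8835C>G
16	23380000	.	C	G	.	PASS	GENE=SCNN1B;CONSEQ=missense;PROBAND=P8;HGVSC=c.1853C>G
17	15133000	.	C	T	.	PASS	GENE=PMP22;CONSEQ=missense;PROBAND=P4;HGVSC=c.215C>T
17	15129000	.	N	<DUP>	.	PASS	GENE=PMP22;CONSEQ=other;SVTYPE=DUP;END=15165000;PROBAND=P9;HGVSC=whole_gene_duplication
X	49850000	.	GACTCTGGTTATCAAAACCATC	G	.	PASS	GENE=CLCN5;CONSEQ=inframe_indel;PROBAND=P1;HGVSC=c.778_798delACTCTGGTTATCAAAACCATC
X	7137000	.	N	<DEL>	.	PASS	GENE=STS;CONSEQ=other;SVTYPE=DEL;END=7272000;PROBAND=P2;HGVSC=whole_gene_deletion
X	31137000	.	N	<DEL>	.	PASS	GENE=DMD;CONSEQ=other;SVTYPE=DEL;END=31190000;PROBAND=P6;HGVSC=CDS_10-12_deletion
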