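gene	disease	motif	cutoff_units	cutoff_bp	region_class	chrom	start	end	interruption_motifs	zygosity	motif_change
AR	Spinal and bulbar muscular atrophy	CAG	36	108	coding	chrX	1000000	1000063		monoallelic	false
ATN1	Dentatorubral-pallidoluysian atrophy	CAG	35	105	coding	chr12	1050000	1050045		monoallelic	false
ATXN10	Spinocerebellar ataxia 10	ATTCT	33	165	intron	chr22	1100000	1100070		monoallelic	false
ATXN1	Spinocerebellar ataxia 1	CAG	39	117	coding	chr6	1150000	1150087	CAT	monoallelic	false
ATXN2	Spinocerebellar ataxia 2	CAG	32	96	coding	chr12	1200000	1200066		monoallelic	false
ATXN3	Spinocerebellar ataxia 3	CAG	45	135	coding	chr14	1250000	1250066		monoallelic	false
PHOX2B	Congenital central hypoventilation syndrome	GCN	NA	NA	coding	chr4	1300000	1300060		monoallelic	false
ATXN7	Spinocerebellar ataxia 8	CAG	33	99	coding	chr3	1350000	1350030		monoallelic	false
ATXN8OS	Spinocerebellar ataxia 8	CAG	40	120	utr3	chr13	1400000	1400060		monoallelic	false
C9orf72	Frontotemporal dementia and/or amyotrophic lateral sclerosis	GGGGCC	30	180	intron	chr9	1450000	1450030		monoallelic	false
CACNA1A	Spinocerebellar ataxia 6	CAG	19	57	coding	chr19	1500000	1500033		monoallelic	false
CNBP	Myotonic dystrophy 2	CCTG	27	108	intron	chr3	1550000	1550060		monoallelic	false
DMPK	Myotonic dystrophy 1	CTG	36	108	utr3	chr19	1600000	1600036		monoallelic	false
FMR1	FMR1-related disorders	CGG	55	165	utr5	chrX	1650000	1650090		monoallelic	false
FXN	Friedreich ataxia	GAA	34	102	intron	chr9	1700000	1700027		monoallelic	false
HTT	Huntington disease	CAG	35	105	coding	chr4	1750000	1750054		monoallelic	false
JPH3	Huntington disease-like 2	CTG	49	147	coding	chr16	1800000	1800042		monoallelic	false
NOP56	Spinocerebellar ataxia 36	GGCCTG	15	90	intron	chr20	1850000	1850042		monoallelic	false
PPP2R2B	Spinocerebellar ataxia 12	CAG	33	99	utr5	chr5	1900000	1900039		monoallelic	false
TBP	Spinocerebellar ataxia 17	CAG	43	129	coding	chr6	1950000	1950105		monoallelic	false
NIPA1	Hereditary spastic paraplegia type 6	GCG	NA	NA	utr5	chr15	2000000	2000021		monoallelic	false
NOTCH2NL	Neuronal intranuclear inclusion disease	GGC	55	165	utr5	chr1	2050000	2050045		monoallelic	false
RFC1	Cerebellar ataxia, neuropathy, and vestibular areflexia syndrome	AAGGG	0	5	intron	chr4	2100000	2100055		monoallelic	true
PABN1	Oculopharyngeal muscular dystrophy	GCN	NA	NA	coding	chr14	2150000	2150030		monoallelic	false
CSTB	Progressive myoclonic epilepsy 1A	CCCCGCCCCGCG	4	48	intron	chr21	2200000	2200036		monoallelic	false
GLS	Global developmental delay, progressive ataxia, and elevated glutamine	GCA	30	90	utr5	chr2	2250000	2250042		biallelic	false
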