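snp_id	chrom	pos	gene	short_allele	long_allele	beta	ref_eaf
rs11125529	2	54475866	ACYP2	A	C	0.065	0.129
rs6772228	3	58376019	PXK	T	A	0.041	0.948
rs10936599	3	169492101	TERC	C	T	0.100	0.737
rs7675998	4	164007820	NAF1	G	A	0.048	0.766
rs2736100	5	1286516	TERT	C	A	0.085	0.480
rs9420907	10	105676465	OBFC1	C	A	0.142	0.130
rs3027234	17	8136092	CTC1	C	T	0.103	0.762
rs8105767	19	22215441	ZNF208	G	A	0.064	0.283
rs412658	19	22359440	ZNF676	T	C	0.086	0.344
rs6028466	20	38129002	DHX35	A	G	0.058	0.059
rs755017	20	62421622	ZBTB46	G	A	0.019	0.132
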