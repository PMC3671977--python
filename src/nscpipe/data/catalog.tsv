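# Protein catalog of the packaged seminal-plasma study fixture.
# accession = NCBI database index number (primary key); aliases = alternate
# accessions (other isoforms / duplicate database entries) whose count rows
# are merged into the primary record.
accession	uniprot	name	mw_kda	pi	aliases
4505821	P12273	prolactin-induced protein	16	8.2
4506885	Q02383	semenogelin II precursor	65	9
4502027	P02768	albumin preproprotein	71	5.9
54607120	P02788	lactotransferrin	80	8.5
5453678	P61916	epididymal secretory protein E1 precursor	16	7.5
221316614	Q16610	extracellular matrix protein 1 isoform 1 precursor	62	6.2	4758236
11386147	P07602	prosaposin isoform a preproprotein	59	5
4503143	P07339	cathepsin D preproprotein	45	6.1
4502173	Q546G3	prostate specific antigen isoform 1 preproprotein	29	7.6	71834855
4502337	P25311	zinc alpha-2-glycoprotein 1	34	5.7
42716297	P10909	clusterin isoform 1	58	6.2
151301154	Q6W4X9	mucin 6, gastric	263	7.2	89033736
4503109	P01036	cystatin S precursor	16	4.9
5031863	Q08380	galectin 3 binding protein	66	5.1
38049014	P04279	semenogelin I isoform b preproprotein	45	9.2
6382064	P15309	prostatic acid phosphatase precursor	44	5.8
4503107	P01034	cystatin C precursor	16	9
4507509	Q6FGX5	tissue inhibitor of metalloproteinase 1 precursor	23	8.4
4757826	P61769	beta 2 microglobulin precursor	13	6
31543380	Q99497	DJ-1 protein	20	6.3
56676397	Q6UB99	ankyrin repeat domain 11	299	6.7
167857790	P02763	orosomucoid 1 precursor	23	5
50363217	P01009	serine proteinase inhibitor, clade A, member 1	46	5.3
4557871	Q06AH7	transferrin	79	6.8
4507065	P03973	secretory leukocyte peptidase inhibitor precursor	15	9.1
4506713	P62979	ubiquitin and ribosomal protein S27a precursor	18	9.6
104487006	Q13332	protein tyrosine phosphatase, receptor type, sigma isoform 1 precursor	218	6.1
25121982	P54107	acidic epididymal glycoprotein-like 1 isoform 1 precursor	29	5.5
32171249	P41222	prostaglandin H2 D-isomerase	21	7.6
4503139	P07858	cathepsin B preproprotein	38	5.8
19923082	Q8WXA2	expressed in prostate and testis	14	8.2
4505529	P19652	orosomucoid 2	23	5
110735433	Q8N6Q3	CD177 molecule	47	5.6
4503009	P16870	carboxypeptidase E preproprotein	53	5
47132551	P02751	fibronectin 1 isoform 2 preproprotein	269	5.3	16933542
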