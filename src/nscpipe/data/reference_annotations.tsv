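# Reference classification annotations of the 35-protein seminal-plasma
# fixture: per-group presence counts, low-abundance flags, differential-
# expression calls versus the NN baseline, and per-group significance.
# n_samples_printed is the total-sample figure as originally tabulated and
# may disagree with the presence columns (kept verbatim; presence columns
# are authoritative).  dep entries are comma-joined comparison:direction.
accession	name	n_samples_printed	present_NN	present_NA	present_OA	present_ON	low_global	low_groups	dep	significant_groups	notes
4505821	prolactin-induced protein	12	5	4	2	1	0			NN,NA,OA,ON
4506885	semenogelin II precursor	12	5	4	2	1	0			NN,NA,OA,ON
4502027	albumin preproprotein	12	5	4	2	1	0			NN,NA,OA,ON
54607120	lactotransferrin	12	5	4	2	1	0			NN,NA,OA,ON
5453678	epididymal secretory protein E1 precursor	12	5	4	2	1	0			NN,NA,OA,ON
221316614	extracellular matrix protein 1 isoform 1 precursor	12	5	4	2	1	0			NN,NA,OA,ON
11386147	prosaposin isoform a preproprotein	12	5	4	2	1	0			NN,NA,OA,ON
4503143	cathepsin D preproprotein	12	5	4	2	1	0			NN,NA,OA,ON
4502173	prostate specific antigen isoform 1 preproprotein	12	5	4	2	1	0		OA:up	NN,NA,OA,ON
4502337	zinc alpha-2-glycoprotein 1	12	5	4	2	1	0		ON:up	NN,NA,OA,ON
42716297	clusterin isoform 1	12	5	4	2	1	0	ON	ON:down	NN,NA,OA
151301154	mucin 6, gastric	11	4	4	2	1	0		NA:down	NN,NA,OA,ON
4503109	cystatin S precursor	11	4	4	2	1	0	ON	NA:down,OA:down,ON:down	NN,NA,OA
5031863	galectin 3 binding protein	11	5	3	2	1	0	OA,ON	OA:down,ON:down	NN,NA
38049014	semenogelin I isoform b preproprotein	10	3	4	2	1	0		OA:up	NN,NA,OA,ON
6382064	prostatic acid phosphatase precursor	10	4	3	2	1	0	ON	NA:down,ON:down	NN,NA,OA
4503107	cystatin C precursor	9	4	3	1	1	0		OA:down	NN,NA,OA,ON
4507509	tissue inhibitor of metalloproteinase 1 precursor	8	3	3	1	1	0		ON:up	NN,NA,OA,ON
4757826	beta 2 microglobulin precursor	8	3	3	1	1	0	OA	OA:down,ON:up	NN,NA,ON
31543380	DJ-1 protein	6	2	3	0	1	0		NA:up,ON:up	NN,NA,ON
56676397	ankyrin repeat domain 11	4	0	1	2	1	0	NA,ON	OA:down,ON:down	OA	absent in baseline; see relaxations
167857790	orosomucoid 1 precursor	2	2	1	0	0	0	NA	NA:down	NN	printed total 2 disagrees with presence columns
50363217	serine proteinase inhibitor, clade A, member 1	8	3	3	1	1	0		NA:up,OA:down,ON:up	NA,OA,ON	OA down-call implies NN significance; see relaxations
4557871	transferrin	6	2	3	1	0	1		NA:up,OA:up
4507065	secretory leukocyte peptidase inhibitor precursor	5	1	3	1	0	1		NA:up,OA:up
4506713	ubiquitin and ribosomal protein S27a precursor	4	2	1	1	0	1		NA:down,OA:down
104487006	protein tyrosine phosphatase, receptor type, sigma isoform 1 precursor	4	1	2	0	1	1		NA:up,ON:up
25121982	acidic epididymal glycoprotein-like 1 isoform 1 precursor	3	2	1	0	0	1		NA:down
32171249	prostaglandin H2 D-isomerase	5	2	2	1	0	1
4503139	cathepsin B preproprotein	6	3	3	0	0	1
19923082	expressed in prostate and testis	4	2	1	1	0	1
4505529	orosomucoid 2	1	1	0	0	0	1
110735433	CD177 molecule	3	0	1	1	1	1				ON presence cell ambiguous in source table; read as 1
4503009	carboxypeptidase E preproprotein	9	3	3	2	1	0	OA,ON		NN,NA
47132551	fibronectin 1 isoform 2 preproprotein	10	4	4	1	1	0	ON		NN,NA,OA
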