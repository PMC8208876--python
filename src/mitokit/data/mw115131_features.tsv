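name	type	start	end	strand	n_exons	exons	nested_in
Cytochrome b	CDS	160	8182	reverse	5		
LAGLIDADG/HNH endonuclease	CDS	7429	7776	reverse	1		Cytochrome b
NADH dehydrogenase subunit 5	CDS	8432	10405	reverse	1		
NADH dehydrogenase subunit 4 L	CDS	10405	10680	reverse	1		
Cytochrome c oxidase subunit II	CDS	10896	13952	reverse	6		
ATP synthase F0 subunit c	CDS	14052	14237	reverse	1		
NADH dehydrogenase subunit 3	CDS	14315	14968	reverse	2		
LAGLIDADG endonuclease	CDS	14683	14880	reverse	1		NADH dehydrogenase subunit 3
NADH dehydrogenase subunit 2	CDS	14969	18193	reverse	2		
Hypothetical protein	CDS	15626	16390	reverse	1		NADH dehydrogenase subunit 2
tRNA-Met	tRNA	18210	18283	reverse	1		
tRNA-His	tRNA	18325	18398	reverse	1		
tRNA-Leu	tRNA	18485	18569	reverse	1		
tRNA-Lys	tRNA	18570	18642	reverse	1		
tRNA-Phe	tRNA	18643	18715	reverse	1		
tRNA-Leu	tRNA	19673	19755	reverse	1		
tRNA-Met	tRNA	19758	19830	reverse	1		
tRNA-Glu	tRNA	19904	19976	reverse	1		
Large subunit rRNA	rRNA	20067	27337	reverse	3		
Ribosomal protein S3	CDS	20672	21916	reverse	1		Large subunit rRNA
tRNA-Pro	tRNA	27400	27471	reverse	1		
NADH dehydrogenase subunit 6	CDS	27677	28441	reverse	1		
tRNA-Gly	tRNA	28544	28614	reverse	1		
Cytochrome c oxidase subunit III	CDS	29224	32387	reverse	3		
Intron-encoded endonuclease aI1	CDS	29932	30138	reverse	1		Cytochrome c oxidase subunit III
Hypothetical protein	CDS	30395	30664	reverse	1		Cytochrome c oxidase subunit III
Alpha-beta-hydrolase	CDS	30423	30686	forward	1		Cytochrome c oxidase subunit III
tRNA-Asn	tRNA	32437	32508	reverse	1		
Small subunit rRNA	rRNA	34254	35615	reverse	1		
ATP synthase F0 subunit a	CDS	35918	38001	reverse	2		
ATP synthase F0 subunit 8	CDS	38061	38237	reverse	1		
NADH dehydrogenase subunit 4	CDS	38620	40035	reverse	1		
NADH dehydrogenase subunit 1	CDS	40119	42582	reverse	4		
tRNA-Arg	tRNA	42726	42799	reverse	1		
Cytochrome c oxidase subunit I	CDS	42809	55293	reverse	7		
LAGLIDADG endonuclease (QPC56057.1)	CDS	43660	44880	reverse	1		Cytochrome c oxidase subunit I
LAGLIDADG endonuclease (QPC56058.1)	CDS	45125	46054	reverse	1		Cytochrome c oxidase subunit I
LAGLIDADG endonuclease (QPC56054.1)	CDS	46857	48248	reverse	1		Cytochrome c oxidase subunit I
LAGLIDADG endonuclease (QPC56060.1)	CDS	48620	49483	reverse	1		Cytochrome c oxidase subunit I
LAGLIDADG endonuclease (QPC56055.1)	CDS	49525	50814	reverse	1		Cytochrome c oxidase subunit I
LAGLIDADG endonuclease (QPC56059.1)	CDS	50865	51734	reverse	1		Cytochrome c oxidase subunit I
Hypothetical protein	CDS	54290	54850	forward	1		
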