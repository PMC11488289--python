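# Gene-name alias map, version 1.
# alias<TAB>canonical — matching is case-insensitive and ignores punctuation,
# so one row covers e.g. "trnL-uur", "trnL(uur)" and "TRNL UUR".
COI	cox1
CO1	cox1
COXI	cox1
cytochrome c oxidase subunit I	cox1
cytochrome c oxidase subunit 1	cox1
cytochrome oxidase subunit I	cox1
COII	cox2
CO2	cox2
COXII	cox2
cytochrome c oxidase subunit II	cox2
cytochrome c oxidase subunit 2	cox2
COIII	cox3
CO3	cox3
COXIII	cox3
cytochrome c oxidase subunit III	cox3
cytochrome c oxidase subunit 3	cox3
CYTB	cob
CYB	cob
cytb	cob
cytochrome b	cob
cytochrome-b	cob
ND1	nad1
NADH1	nad1
NADH dehydrogenase subunit 1	nad1
ND2	nad2
NADH2	nad2
NADH dehydrogenase subunit 2	nad2
ND3	nad3
NADH3	nad3
NADH dehydrogenase subunit 3	nad3
ND4	nad4
NADH4	nad4
NADH dehydrogenase subunit 4	nad4
ND4L	nad4L
nad4l	nad4L
NADH4L	nad4L
NADH dehydrogenase subunit 4L	nad4L
ND5	nad5
NADH5	nad5
NADH dehydrogenase subunit 5	nad5
ND6	nad6
NADH6	nad6
NADH dehydrogenase subunit 6	nad6
ATPase6	atp6
ATP synthase F0 subunit 6	atp6
ATPase subunit 6	atp6
ATPase8	atp8
ATP synthase F0 subunit 8	atp8
ATPase subunit 8	atp8
12S	rrnS
rrn12	rrnS
12S rRNA	rrnS
12S ribosomal RNA	rrnS
s-rRNA	rrnS
srRNA	rrnS
small subunit ribosomal RNA	rrnS
rns	rrnS
16S	rrnL
rrn16	rrnL
16S rRNA	rrnL
16S ribosomal RNA	rrnL
l-rRNA	rrnL
lrRNA	rrnL
large subunit ribosomal RNA	rrnL
rnl	rrnL
trnA	A
tRNA-Ala	A
trnC	C
tRNA-Cys	C
trnD	D
tRNA-Asp	D
trnE	E
tRNA-Glu	E
trnF	F
tRNA-Phe	F
trnG	G
tRNA-Gly	G
trnH	H
tRNA-His	H
trnI	I
tRNA-Ile	I
trnK	K
tRNA-Lys	K
trnL1	L1
trnL-cun	L1
trnL(cun)	L1
tRNA-Leu(CUN)	L1
trnL-tag	L1
trnL2	L2
trnL-uur	L2
trnL(uur)	L2
tRNA-Leu(UUR)	L2
trnL-taa	L2
trnM	M
tRNA-Met	M
trnN	N
tRNA-Asn	N
trnP	P
tRNA-Pro	P
trnQ	Q
tRNA-Gln	Q
trnR	R
tRNA-Arg	R
trnS1	S1
trnS-agn	S1
trnS(agn)	S1
tRNA-Ser(AGN)	S1
trnS-gct	S1
trnS2	S2
trnS-ucn	S2
trnS(ucn)	S2
tRNA-Ser(UCN)	S2
trnS-tga	S2
trnT	T
tRNA-Thr	T
trnV	V
tRNA-Val	V
trnW	W
tRNA-Trp	W
trnY	Y
tRNA-Tyr	Y
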