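##CanRisk 2.0
##FamID	Name	Target	IndivID	FathID	MothID	Sex	MZtwin	Dead	Age	Yob	BC1	BC2	OC	PRO	PAN	Ashkn	BRCA1	BRCA2	PALB2	ATM	CHEK2	BARD1	RAD51B	RAD51C	RAD51D	ER:PR:HER2:CK14:CK56
DEMO	GF	0	GF	0	0	M	0	1	82	0	0	0	0	0	0	0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0:0:0:0
DEMO	GM	0	GM	0	0	F	0	1	70	0	55	0	0	0	0	0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0:0:0:0
DEMO	QUERY	0	QUERY	GF	GM	F	0	0	81	0	0	0	0	0	0	0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0:0:0:0
DEMO	MOM	0	MOM	GF	GM	F	0	0	62	0	45	0	0	0	0	0	S:P	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0:0:0:0
DEMO	AUNT1	0	AUNT1	GF	GM	F	0	0	58	0	52	0	0	0	0	0	S:P	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0:0:0:0
DEMO	DAD	0	DAD	0	0	M	0	0	65	0	0	0	0	0	0	0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0:0:0:0
DEMO	AU1SP	0	AU1SP	0	0	M	0	0	60	0	0	0	0	0	0	0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0:0:0:0
DEMO	PB	1	PB	DAD	MOM	F	0	0	42	0	40	0	0	0	0	0	S:P	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0:0:0:0
DEMO	COUS	0	COUS	AU1SP	AUNT1	F	0	0	50	0	0	0	0	0	0	0	S:N	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0	0:0:0:0:0
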