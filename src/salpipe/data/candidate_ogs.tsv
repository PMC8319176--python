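og_id	locus_tag	cog_category	annotation
07TNN	SPO0365	S	Domain of unknown function (DUF1989)
05CDD	SPO0716	S	Phospholipid glycerol acyltransferase
01VSN	SPO0838	M	Bacterial sugar transferase
05MEE	SPO0968	L	Nudix hydrolase
05K39	SPO1109	S	Endonuclease exonuclease phosphatase
05NU0	SPO1287	S	Glyoxalase bleomycin resistance protein dioxygenase
08EFD	SPO1424	P	Sodium hydrogen exchanger
08K1F	SPO1437	I, Q	Dehydrogenase
05D82	SPO1743	E	Glutamate dehydrogenase
05S99	SPO1919	P	Tellurite resistance protein
090P8	SPO1963	G	Phosphoglycerate mutase
05N59	SPO2284	M	Transglycosylase
01QFF	SPO2332	P	Acriflavin resistance protein
08YCB	SPO2344	E	Sarcosine oxidase, gamma subunit
08UX5	SPO2471	S	Acetyltransferase, (GNAT) family
01QH6	SPO2697	C	CoA-binding domain protein
07QRG	SPO2741	L	DNA polymerase iii
05X3J	SPO2754	S	Uncharacterized protein
060TV	SPO2757	S	EF hand domain protein
01TDR	SPO2815	P	ABC transporter permease protein
08TCB	SPO3054	S	Uncharacterized protein
0808N	SPO3431	S	Domain of unknown function (DUF3576)
08RQB	SPO3439	I	Enoyl-coA hydratase isomerase family protein
08R76	SPO3444	M	3-deoxy-d-manno-octulosonic-acid transferase
07RFB	SPO3740	O	Catalyzes the reversible oxidation-reduction of methionine sulfoxide in proteins to methionine
6405	SPO0725	S	SH3 type 3
01RKE	SPO2816	P	ABC transporter permease protein
05DM9	SPO0035	S	Core-2 I-branching enzyme family protein
0627S	SPO_RS14095	S	Uncharacterized protein
07SF7	SPO2814	E	Peptide opine nickel uptake family ABC transporter periplasmic substrate-binding protein
05SH6	SPO3502	S	DUF3118 protein
08U9J	SPO3819	S	Type I secretion target repeat protein
05WTG	SPO2776	S	Uncharacterized protein
05Q6E	SPO3716	S	Uncharacterized protein
08T58	SPO3836	S	Mg2+ transport protein CorA
064YK	SPO1241	S	Uncharacterized protein
05U51	SPO0776	S	Thioesterase
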