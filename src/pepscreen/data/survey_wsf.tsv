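sequence	fraction	protein_name	accession	28	90	180	270	360
AGFAGDDAPR	WSF	Actin	P68137; ACTA1	+	-	-	+	+
AGLKPGEL	WSF	Phosphoglyceratemutase	B5KJG2; PGAM2	+	+	+	-	-
ALESPERPF	WSF	Phosphoglyceratekinase	F1RPH0; PGK1	+	+	+	+	+
DQALKPTKPM	WSF	Phosphoglyceratemutase	B5KJG2; PGAM2	+	-	+	+	+
ELDQALKPTKPM	WSF	Phosphoglyceratemutase	Q32KV0; PGAM2	-	-	+	+	+
GVDNPGHPF	WSF	Creatinekinase	Q2HYU1; CKMT2	+	+	+	-	-
IFQEVIDLGGEAIK	WSF	Alpha-amylase	P00689; AMY2	-	+	-	+	+
IQLVEEELDRA	WSF	Tropomyosin alpha-3 chain	A1XQV4; TPM3	+	-	-	+	+
KDLFDPIIQDR	WSF	Creatine kinase M-type	Q5XLD3; CKM	+	-	-	+	+
KVVDVGSKV	WSF	Pyruvate kinase PKM	P11974; PKM	+	+	-	-	+
LDQALKPTKPM	WSF	Phosphoglyceratemutase	B5KJG2; PGAM2	+	-	+	+	+
LFDKPVSPI	WSF	Creatine kinase B-type	Q29594; CKB	+	+	+	-	-
LFDKPVSPL	WSF	Creatinekinase	Q2HYU1; CKMT2	+	+	+	+	+
MSHLGRPDGIPMPD	WSF	Phosphoglyceratekinase	F1RPH0; PGK1	+	+	-	+	-
MSHLGRPDGIPMPDK	WSF	Phosphoglyceratekinase	F1RPH0; PGK1	+	+	+	-	+
NLHPELGTDADKEH	WSF	L-lactate dehydrogenase A chain	P00339; LDHA	+	-	-	+	+
PEILPDGDHD	WSF	Fructose-bisphosphate aldolase	F1RJ25; ALDOC	+	+	+	+	+
PEILPDGDHDL	WSF	Fructose-bisphosphate aldolase	F1RJ25; ALDOC	+	+	+	+	+
PEILPDGDHDLK	WSF	Fructose-bisphosphate aldolase	F1RJ25; ALDOC	+	+	+	+	+
SAPILNIPI	WSF	Transmembrane protein 41A	I3LPS6; TMEM41A	+	+	+	-	-
SAPILNIPIV	WSF	Transmembrane protein 41A	I3LPS6; TMEM41A	+	+	+	-	+
SFDIPPPPMD	WSF	Phosphoglyceratemutase	Q32KV0; PGAM2	-	+	+	+	+
SFDIPPPPMDEK	WSF	Phosphoglyceratemutase	Q32KV0; PGAM2	+	-	+	+	+
SISNSAEDPFIAIH	WSF	Alpha-amylase	F1S574; AMY2	-	+	-	+	+
VDLPAVSEK	WSF	Multifunctional fusion protein	F1SHL9; PKM	+	-	-	+	+
VGVNLPK	WSF	Phosphoglyceratekinase	F1RPH0; PGK1	+	+	+	+	-
VPAPVEIPVTPPTLVSGLK	WSF	Titin	Q8WZ42; TTN	+	-	+	-	+
WILGEHGDSSVPV	WSF	L-lactate dehydrogenase A chain	P00339; LDHA	+	+	-	-	+
WTIAVPGPPH	WSF	Myomesin 1	F1SM75; MYOM1	+	-	+	+	+
WTIAVPGPPHS	WSF	Myomesin 1	F1SM75; MYOM1	-	-	+	+	+
YDQLPEPR	WSF	Serotransferrin	P09571; TF	-	+	+	-	+
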