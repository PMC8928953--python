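sequence	fraction	protein_name	accession	28	90	180	270	360
AGFAGDDAPR	SSF	Actin, alpha skeletal muscle	P68137; ACTA1	+	-	+	+	+
FDKPVSPL	SSF	Creatine kinase M-type	Q5XLD3; CKM	+	+	+	-	-
FKRPLP	SSF	Mediator of RNA polymerase II transcription subunit 17	F1STK7; MED17	+	+	+	-	-
FKRPPI	SSF	ribonuclease P/MRP subunit p30	F1SCX5; RPP30	+	+	+	-	-
FKRPPL	SSF	Troponin I	I3LB76; TTI1	+	+	+	-	-
FRVPTPNVSV	SSF	Glyceraldehyde-3-phosphate dehydrogenase	P00355; GAPDH	+	+	-	+	-
IIAPPER	SSF	Actin, alpha skeletal muscle	P68137; ACTA1	+	+	+	-	-
KDLFDPIIQD	SSF	Creatine kinase M-type	Q5XLD3; CKM	+	+	-	+	-
LGEHNIDVLEGNEQFINAAK	SSF	Trypsin	P00761	+	+	-	+	-
LTEAPLNPK	SSF	Actin, alpha skeletal muscle	P68137; ACTA1	+	+	-	+	-
LVIIESDLER	SSF	Tropomyosin alpha-1 chain	P42639; TPM1	+	-	-	+	+
PEILPDGDHDL	SSF	Fructose-bisphosphate aldolase	P09972; ALDOC	+	+	-	+	-
PEILPDGDHDLK	SSF	Fructose-bisphosphate aldolase	P09972; ALDOC	+	+	-	+	-
PVTIPDKPNSE	SSF	Calsequestrin-1	P31415; CASQ	-	+	+	+	-
PVTIPDKPNSEE	SSF	Calsequestrin-1	P31415; CASQ	-	+	+	+	-
RVVDVPDPPEA	SSF	Myosin binding protein C2	F1RH19; MYBPC2	+	+	+	-	-
VDDLEGSLEQEK	SSF	Myosin-7	P79293; MYH7	+	+	-	+	-
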