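parent	fragment	smiles	probability
WTIAVPGPPHS	GP	NCC(=O)N1[C@@]([H])(CCC1)C(=O)O	0.1334
WTIAVPGPPHS	PP	N1[C@]([H])(CCC1)C(=O)N1[C@]([H])(CCC1)C(=O)O	0.3095
WTIAVPGPPHS	VP	N[C@@]([H])(C(C)C)C(=O)N1[C@@]([H])(CCC1)C(=O)O	0.1858
WTIAVPGPPHS	IA	N[C@@]([H])([C@]([H])(CC)C)C(=O)N[C@@]([H])(C)C(=O)O	0.0619
WTIAVPGPPHS	WT	N[C@@H](Cc1c[nH]c2c1cccc2)C(=O)N[C@@]([H])([C@]([H])(O)C)C(=O)O	0.1273
WTIAVPGPPHS	AV	N[C@]([H])(C)C(=O)N[C@]([H])(C(C)C)C(=O)O	0.1684
WTIAVPGPPHS	HS	N[C@H](Cc1c[nH]cn1)C(=O)N[C@]([H])(CO)C(=O)O	0.0000
WTIAVPGPPHS	PG	N1[C@@]([H])(CCC1)C(=O)NCC(=O)O	0.1501
WTIAVPGPPHS	PH	N1[C@@]([H])(CCC1)C(=O)N[C@@H](Cc1c[nH]cn1)C(=O)O	0.0000
WTIAVPGPPHS	TI	N[C@@]([H])([C@]([H])(O)C)C(=O)N[C@@]([H])([C@]([H])(CC)C)C(=O)O	0.0864
FKRPPL	PP	N1[C@]([H])(CCC1)C(=O)N1[C@]([H])(CCC1)C(=O)O	0.3095
FKRPPL	RP	N[C@]([H])(CCCNC(=N)N)C(=O)N1[C@]([H])(CCC1)C(=O)O	0.1120
FKRPPL	PL	N1[C@]([H])(CCC1)C(=O)N[C@]([H])(CC(C)C)C(=O)O	0.4592
FKRPPL	RPL	N[C@@]([H])(CCCNC(=N)N)C(=O)N1[C@@]([H])(CCC1)C(=O)N[C@@]([H])(CC(C)C)C(=O)O	0.1213
FKRPPL	KR	N[C@]([H])(CCCCN)C(=O)N[C@]([H])(CCCNC(=N)N)C(=O)O	0.0000
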