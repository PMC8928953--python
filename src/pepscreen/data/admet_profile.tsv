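parent	fragment	caco2	hia	ppb	bbb	vd	cyp2d6	t_half	ld50
WTIAVPGPPHS	GP	-5.144	0	13.60	0.629	-0.554	0	0.990	1.904
WTIAVPGPPHS	PP	-5.055	0	25.48	0.716	-0.444	0	0.845	2.423
WTIAVPGPPHS	VP	-5.068	1 (0.504)	38.18	0.624	-0.448	0	0.924	2.423
WTIAVPGPPHS	IA	-5.522	1 (0.616)	23.65	0.864	-0.505	0	1.114	2.158
WTIAVPGPPHS	WT	-6.061	0	53.96	0.956	-0.752	0	0.715	2.211
WTIAVPGPPHS	AV	-5.540	1 (0.553)	28.01	0.932	-0.596	0	1.229	2.058
WTIAVPGPPHS	HS	-1.721	0	13.87	0.909	-0.765	0	0.55	2.401
WTIAVPGPPHS	PG	-5.372	0	15.65	0.899	-0.042	0	0.989	2.020
WTIAVPGPPHS	PH	-5.863	0	20.78	0.910	-0.510	0	0.588	2.535
WTIAVPGPPHS	TI	-5.786	0	35.24	0.749	-0.545	0	1.124	2.371
FKRPPL	PP	-5.055	0	25.48	0.714	-0.444	0	0.845	2.432
FKRPPL	RP	-6.200	0	25.84	0.251	-0.604	0	0.573	2.450
FKRPPL	PL	-5.376	1 (0.510)	45.60	0.830	-0.487	0	0.876	2.382
FKRPPL	RPL	-6.248	0	33.58	0.256	-0.840	1 (substrate)	0.723	2.514
FKRPPL	KR	-6.280	0	32.87	0.523	-0.759	0	0.896	2.328
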