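fraction	sequence	A_printed	fragments_printed
WSF	AGFAGDDAPR	0.5000	FA [3-4], AP [8-9], AG [1-2] [4-5], GF [2-3]
WSF	AGLKPGEL	0.6250	KP [4-5], GL [2-3], AG [1-2], GE [6-7], PG [5-6]
WSF	ALESPERPF	0.5556	SP [4-5], RP [7-8], AL [1-2], ES [3-4], PF [8-9]
WSF	DQALKPTKPM	0.8000	KP [5-6] [8-9], AL [3-4], DQ [1-2], PM [9-10], PT [6-7], QA [2-3], TK [7-8]
WSF	ELDQALKPTKPM	0.6667	KP [7-8] [10-11], AL [5-6], DQ [3-4], PM [11-12], PT [8-9], QA [4-5], TK [9-10]
WSF	GVDNPGHPF	0.8889	HP [7-8], NP [4-5], DN [3-4], GH [6-7], GV [1-2], PF [8-9], PG [5-6], VD [2-3]
WSF	IFQEVIDLGGEAIK	0.4286	EV [4-5], FQ [2-3], GE [10-11], GG [9-10], QE [3-4], VI [5-6]
WSF	IQLVEEELDRA	0.5455	RA [10-11], DR [9-10], IQ [1-2], LV [3-4], QL [2-3], VE [4-5]
WSF	KDLFDPIIQDR	0.5455	DP [5-6], DR [10-11], II [7-8], IQ [8-9], PI [6-7], QD [9-10]
WSF	KVVDVGSKV	0.6667	VV [2-3], KV [1-2] [8-9], SK [7-8], VD [3-4], VG [5-6]
WSF	LDQALKPTKPM	0.7273	KP [6-7] [9-10], AL [4-5], DQ [2-3], PM [10-11], PT [7-8], QA [3-4], TK [8-9]
WSF	LFDKPVSPI	0.5556	SP [7-8], KP [4-5], PI [8-9], PV [5-6], VS [6-7]
WSF	LFDKPVSPL	0.5556	SP [7-8], KP [4-5], PL [8-9], PV [5-6], VS [6-7]
WSF	MSHLGRPDGIPMPD	0.5714	MP [12-13], IP [10-11], RP [6-7], HL [3-4], GI [9-10], PM [11-12], SH [2-3], IPM [10-12]
WSF	MSHLGRPDGIPMPDK	0.5333	MP [12-13], IP [10-11], RP [6-7], HL [3-4], GI [9-10], PM [11-12], SH [2-3], IPM [10-12]
WSF	NLHPELGTDADKEH	0.5000	HP [3-4], AD [10-11], EH [13-14], KE [12-13], LH [2-3], NL [1-2], TD [8-9]
WSF	PEILPDGDHD	0.4000	LP [4-5], EI [2-3], HD [9-10], IL [3-4]
WSF	PEILPDGDHDL	0.3636	LP [4-5], EI [2-3], HD [9-10], IL [3-4]
WSF	PEILPDGDHDLK	0.3333	LP [4-5], EI [2-3], HD [9-10], IL [3-4]
WSF	SAPILNIPI	0.7778	IPI [7-9], AP [2-3], IP [7-8], IL [4-5], LN [5-6], PI [3-4] [8-9]
WSF	SAPILNIPIV	0.7778	IPI [7-9], AP [2-3], IP [7-8], IL [4-5], LN [5-6], PI [3-4] [8-9]
WSF	SFDIPPPPMD	0.7000	PPPP [5-8], PP [5-6] [6-7] [7-8], IP [4-5], PM [8-9], SF [1-2]
WSF	SFDIPPPPMDEK	0.6667	PPPP [5-8], PP [5-6] [6-7] [7-8], IP [4-5], EK [11-12], PM [8-9], SF [1-2]
WSF	SISNSAEDPFIAIH	0.4286	IA [11-12], AE [6-7], DP [8-9], IH [13-14], PF [9-10], SI [1-2]
WSF	VDLPAVSEK	0.6667	PA [4-5], LP [3-4], EK [8-9], AV [5-6], VD [1-2], VS [6-7]
WSF	VGVNLPK	0.8571	LP [5-6], GV [2-3], NL [4-5], PK [6-7], VG [1-2], VN [3-4]
WSF	VPAPVEIPVTPPTLVSGLK	0.8421	PP [11-12], AP [3-4], PA [2-3], VP [1-2], IP [7-8], TP [10-11], GL [17-18], EI [6-7], LV [14-15], PT [12-13], PV [4-5] [8-9], TL [13-14], VE [5-6], VS [15-16], VT [9-10]
WSF	WILGEHGDSSVPV	0.5385	VP [11-12], WI [1-2], EH [5-6], GE [4-5], IL [2-3], PV [12-13], SV [10-11]
WSF	WTIAVPGPPH	0.9000	GP [7-8], PP [8-9], VP [5-6], IA [3-4], WT [1-2], AV [4-5], PG [6-7], PH [9-10], TI [2-3]
WSF	WTIAVPGPPHS	0.9091	GP [7-8], PP [8-9], VP [5-6], IA [3-4], WT [1-2], AV [4-5], HS [10-11], PG [6-7], PH [9-10], TI [2-3]
WSF	YDQLPEPR	0.6250	LP [4-5], EP [6-7], DQ [2-3], QL [3-4], YD [1-2]
SSF	AGFAGDDAPR	0.5000	FA [3-4], AP [8-9], AG [1-2] [4-5], GF [2-3]
SSF	FDKPVSPL	0.6250	SP [6-7], KP [3-4], PL [7-8], PV [4-5], VS [5-6]
SSF	FKRPLP	0.6667	LP [5-6], RP [3-4], PL [4-5], KR [2-3]
SSF	FKRPPI	0.6667	PP [4-5], RP [3-4], KR [2-3], PI [5-6]
SSF	FKRPPL	0.8333	PP [4-5], RP [3-4], PL [5-6], PPL [4-6], KR [2-3]
SSF	FRVPTPNVSV	0.8000	VP [3-4], TP [5-6], FR [1-2], NV [7-8], PN [6-7], PT [4-5], SV [9-10], VS [8-9]
SSF	IIAPPER	0.7143	PP [4-5], AP [3-4], IA [2-3], IIAP [1-4], II [1-2]
SSF	KDLFDPIIQD	0.5000	DP [5-6], II [7-8], IQ [8-9], PI [6-7], QD [9-10]
SSF	LGEHNIDVLEGNEQFINAAK	0.4500	AA [18-19], EG [10-11], EH [3-4], GE [2-3], IN [16-17], NA [17-18], NE [12-13], QF [14-15], VL [8-9]
SSF	LTEAPLNPK	0.7778	AP [4-5], NP [7-8], PL [5-6], LN [6-7], LT [1-2], PK [8-9], TE [2-3]
SSF	LVIIESDLER	0.4000	ES [5-6], II [3-4], LV [1-2], VI [2-3]
SSF	PEILPDGDHDL	0.3636	LP [4-5], EI [2-3], HD [9-10], IL [3-4]
SSF	PEILPDGDHDLK	0.3333	LP [4-5], EI [2-3], HD [9-10], IL [3-4]
SSF	PVTIPDKPNSE	0.5455	IP [4-5], KP [7-8], PN [8-9], PV [1-2], TI [3-4], VT [2-3]
SSF	PVTIPDKPNSEE	0.5000	IP [4-5], KP [7-8], PN [8-9], PV [1-2], TI [3-4], VT [2-3]
SSF	RVVDVPDPPEA	0.4545	PP [8-9], VP [5-6], VV [2-3], DP [7-8], VD [3-4]
SSF	VDDLEGSLEQEK	0.4167	EK [11-12], SL [7-8], EG [5-6], QE [10-11], VD [1-2]
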