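locus	designation	structure
DYS389II	28	[TAGA]11 [CAGA]2 N48 [TAGA]11 [CAGA]4
DYS389II	33	[TAGA]11 [CAGA]3 N48 [TAGA]15 [CAGA]4
DYS390	21	[TAGA]13 [CAGA]8
DYS392	14	[ATA]13 AAA
DYS437	14	[TCTA]8 TCTG CCTG [TCTA]4
DYS437	15	[TCTA]8 [TCTG]3 [TCTA]4
DYS448	19.2	[AGAGAT]11 N38 [AGAGAT]9
DYS448	20	TGAGAT [AGAGAT]11 N42 [AGAGAT]8
DYS448	23	[AGAGAT]14 N42 [AGAGAT]9
DYS460	10	[CTAT]9 GTAT CTAT
DYS533	11	TATC TATA [TATC]9
DYS635	21	[TAGA]9 [TACA]4 [TAGA]2 [TACA]2 [TAGA]4
DYS635	23	[TAGA]11 [TACA]4 [TAGA]2 [TACA]2 [TAGA]4
DYS635	24	[TAGA]12 [TACA]4 [TAGA]2 [TACA]2 [TAGA]4
DYF387S1a/b	38	[AAAG]3 GTAG [GAAG]4 [AAAG]2 GAAG [AAAG]2 [GAAG]7 [AAAG]18
DYF387S1a/b	40	[AAAG]3 GTAG [GAAG]4 [AAAG]2 GAAG AAAG [GAAG]11 [AAAG]17
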