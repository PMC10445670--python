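panel,multiplicity,n_haplotypes
MH,1,1257
MH,2,241
MH,3,72
MH,4,34
MH,5,18
MH,6,12
MH,7,7
MH,8,5
MH,9,3
MH,10,1
MH,11,1
MH,13,1
MH,14,1
MH,18,1
MH,19,2
MH,21,1
MH,24,1
MH,30,1
SWGDAM,1,1544
SWGDAM,2,226
SWGDAM,3,67
SWGDAM,4,21
SWGDAM,5,20
SWGDAM,6,3
SWGDAM,7,2
SWGDAM,8,4
SWGDAM,9,1
SWGDAM,10,3
SWGDAM,13,1
SWGDAM,14,1
SWGDAM,15,1
SWGDAM,22,1
Yfiler,1,1998
Yfiler,2,167
Yfiler,3,31
Yfiler,4,14
Yfiler,5,7
Yfiler,6,1
Yfiler,7,1
Yfiler,9,1
Yfiler,10,1
PPY23,1,2176
PPY23,2,131
PPY23,3,19
PPY23,4,10
PPY23,5,1
PPY23,8,1
Yfiler Plus,1,2323
Yfiler Plus,2,91
Yfiler Plus,3,13
Yfiler Plus,4,1
Ymax,1,2328
Ymax,2,90
Ymax,3,12
Ymax,4,1
full,1,2387
full,2,73
full,3,5
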