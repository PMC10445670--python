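locus,transfers,mutations,one_step,two_step,multi_step,gains,losses
DYS19,2548,7,7,0,0,5,2
DYS388,2548,9,9,0,0,3,6
DYS389I,2548,7,7,0,0,6,1
DYS389II,2548,20,19,1,0,10,10
DYS390,2548,6,6,0,0,2,4
DYS391,2548,4,4,0,0,2,2
DYS392,2548,0,0,0,0,0,0
DYS393,2548,3,3,0,0,1,2
DYS437,2548,2,2,0,0,0,2
DYS438,2548,2,2,0,0,2,0
DYS439,2548,4,4,0,0,1,3
DYS444,2548,4,4,0,0,1,3
DYS447,2548,6,5,1,0,1,5
DYS448,2548,2,2,0,0,1,1
DYS449,2548,23,23,0,0,18,5
DYS456,2548,9,9,0,0,4,5
DYS458,2548,11,10,1,0,6,5
DYS460,2548,9,9,0,0,3,6
DYS481,2548,5,5,0,0,3,2
DYS518,2548,23,22,0,1,10,13
DYS522,2548,4,4,0,0,1,3
DYS549,2548,2,2,0,0,0,2
DYS533,2548,8,8,0,0,3,5
DYS557,2548,8,8,0,0,5,3
DYS570,2548,13,12,1,0,6,7
DYS576,2548,27,27,0,0,10,17
DYS593,2548,3,3,0,0,2,1
DYS596,2548,0,0,0,0,0,0
DYS627,2548,32,31,1,0,14,18
DYS635,2548,11,11,0,0,5,6
DYS643,2548,3,3,0,0,1,2
DYS645,2548,5,5,0,0,1,4
Y-GATA-H4,2548,8,8,0,0,4,4
DYF387S1a/b,5096,25,23,0,2,15,10
DYF404S1a/b,5096,17,16,1,0,6,11
DYS385a/b,5096,13,12,1,0,9,4
DYS527a/b,5096,21,19,1,1,12,9
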