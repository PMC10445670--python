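# Combined Y-STR systems used for panel-wise haplotype statistics.
#
# n_l is the locus count as conventionally reported for the system
# (dual-copy markers counted twice).  For PowerPlex Y23 the reported
# count (25) exceeds the 24 loci of the standard kit definition shipped
# here; the reported value is carried as metadata and the expanded size
# of the locus list is available separately.
panels:
  MH:
    n_l: 9
    loci: [DYS19, DYS385a/b, DYS389I, DYS389II, DYS390, DYS391, DYS392, DYS393]
  SWGDAM:
    n_l: 11
    loci: [DYS19, DYS385a/b, DYS389I, DYS389II, DYS390, DYS391, DYS392, DYS393,
           DYS438, DYS439]
  Yfiler:
    n_l: 17
    loci: [DYS19, DYS385a/b, DYS389I, DYS389II, DYS390, DYS391, DYS392, DYS393,
           DYS438, DYS439, DYS437, DYS448, DYS456, DYS458, DYS635, Y-GATA-H4]
  PPY23:
    n_l: 25
    loci: [DYS19, DYS385a/b, DYS389I, DYS389II, DYS390, DYS391, DYS392, DYS393,
           DYS438, DYS439, DYS437, DYS448, DYS456, DYS458, DYS635, Y-GATA-H4,
           DYS481, DYS533, DYS549, DYS570, DYS576, DYS643]
  Yfiler Plus:
    n_l: 27
    loci: [DYS19, DYS385a/b, DYS389I, DYS389II, DYS390, DYS391, DYS392, DYS393,
           DYS438, DYS439, DYS437, DYS448, DYS456, DYS458, DYS635, Y-GATA-H4,
           DYS449, DYS460, DYS481, DYS518, DYS533, DYS570, DYS576, DYS627,
           DYF387S1a/b]
  Ymax:
    n_l: 29
    loci: [DYS19, DYS385a/b, DYS389I, DYS389II, DYS390, DYS391, DYS392, DYS393,
           DYS438, DYS439, DYS437, DYS448, DYS456, DYS458, DYS635, Y-GATA-H4,
           DYS449, DYS460, DYS481, DYS518, DYS533, DYS570, DYS576, DYS627,
           DYF387S1a/b, DYS549, DYS643]
  full:
    n_l: 41
    loci: [DYS19, DYS388, DYS389I, DYS389II, DYS390, DYS391, DYS392, DYS393,
           DYS437, DYS438, DYS439, DYS444, DYS447, DYS448, DYS449, DYS456,
           DYS458, DYS460, DYS481, DYS518, DYS522, DYS549, DYS533, DYS557,
           DYS570, DYS576, DYS593, DYS596, DYS627, DYS635, DYS643, DYS645,
           Y-GATA-H4, DYF387S1a/b, DYF404S1a/b, DYS385a/b, DYS527a/b]
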