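# Registry of the 41 Y-STR loci of the 41-plex CE kit.
#
# Dual-copy markers (DYF387S1a/b, DYF404S1a/b, DYS385a/b, DYS527a/b) are one
# entry each with copy_number 2, so 37 entries describe 41 loci.
#
# motif_class (simple / compound / complex) is a provisional assignment from
# published repeat-structure descriptions; edit to match your kit's
# nomenclature sheet if it differs.  rm_status: RM marks the initially
# defined rapidly mutating panel; the other bands (fast >=5e-3, moderate
# 1e-3..5e-3, slow <1e-3) follow the conventional rate cut-offs.
# typical_allele is a modal repeat number used only to seed simulations.
#
# designation rules: repeat blocks and full-length single units are counted;
# spacers are not.  canonical_spacer_bp triggers microvariant (.x) naming
# when the observed spacer total deviates from it.  designation_offset
# shifts the counted total for loci whose nomenclature excludes a block.
loci:
  DYS19:        {copy_number: 1, unit_length_bp: 4, motif_class: compound, rm_status: moderate, typical_allele: 15}
  DYS388:       {copy_number: 1, unit_length_bp: 3, motif_class: simple,   rm_status: moderate, typical_allele: 12}
  DYS389I:      {copy_number: 1, unit_length_bp: 4, motif_class: compound, rm_status: moderate, typical_allele: 13}
  DYS389II:     {copy_number: 1, unit_length_bp: 4, motif_class: compound, rm_status: fast,     typical_allele: 29}
  DYS390:       {copy_number: 1, unit_length_bp: 4, motif_class: compound, rm_status: moderate, typical_allele: 24}
  DYS391:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: moderate, typical_allele: 10}
  DYS392:       {copy_number: 1, unit_length_bp: 3, motif_class: compound, rm_status: slow,     typical_allele: 13}
  DYS393:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: moderate, typical_allele: 13}
  DYS437:       {copy_number: 1, unit_length_bp: 4, motif_class: compound, rm_status: slow,     typical_allele: 14}
  DYS438:       {copy_number: 1, unit_length_bp: 5, motif_class: simple,   rm_status: slow,     typical_allele: 10}
  DYS439:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: moderate, typical_allele: 12}
  DYS444:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: moderate, typical_allele: 12}
  DYS447:       {copy_number: 1, unit_length_bp: 5, motif_class: complex,  rm_status: moderate, typical_allele: 25}
  DYS448:       {copy_number: 1, unit_length_bp: 6, motif_class: complex,  rm_status: slow,     typical_allele: 19,
                 canonical_spacer_bp: 42}
  DYS449:       {copy_number: 1, unit_length_bp: 4, motif_class: complex,  rm_status: RM,       typical_allele: 29}
  DYS456:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: moderate, typical_allele: 15}
  DYS458:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: moderate, typical_allele: 17}
  DYS460:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: moderate, typical_allele: 10,
                 designation_offset: -1}
  DYS481:       {copy_number: 1, unit_length_bp: 3, motif_class: simple,   rm_status: moderate, typical_allele: 23}
  DYS518:       {copy_number: 1, unit_length_bp: 4, motif_class: complex,  rm_status: RM,       typical_allele: 38}
  DYS522:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: moderate, typical_allele: 11}
  DYS549:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: slow,     typical_allele: 12}
  DYS533:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: moderate, typical_allele: 11}
  DYS557:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: moderate, typical_allele: 15}
  DYS570:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: RM,       typical_allele: 17}
  DYS576:       {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: RM,       typical_allele: 18}
  DYS593:       {copy_number: 1, unit_length_bp: 5, motif_class: simple,   rm_status: moderate, typical_allele: 15}
  DYS596:       {copy_number: 1, unit_length_bp: 6, motif_class: simple,   rm_status: slow,     typical_allele: 11}
  DYS627:       {copy_number: 1, unit_length_bp: 4, motif_class: complex,  rm_status: RM,       typical_allele: 21}
  DYS635:       {copy_number: 1, unit_length_bp: 4, motif_class: compound, rm_status: moderate, typical_allele: 21}
  DYS643:       {copy_number: 1, unit_length_bp: 5, motif_class: simple,   rm_status: moderate, typical_allele: 10}
  DYS645:       {copy_number: 1, unit_length_bp: 5, motif_class: simple,   rm_status: moderate, typical_allele: 8}
  Y-GATA-H4:    {copy_number: 1, unit_length_bp: 4, motif_class: simple,   rm_status: moderate, typical_allele: 12}
  DYF387S1a/b:  {copy_number: 2, unit_length_bp: 4, motif_class: complex,  rm_status: RM,       typical_allele: 37}
  DYF404S1a/b:  {copy_number: 2, unit_length_bp: 4, motif_class: simple,   rm_status: RM,       typical_allele: 13}
  DYS385a/b:    {copy_number: 2, unit_length_bp: 4, motif_class: simple,   rm_status: moderate, typical_allele: 13}
  DYS527a/b:    {copy_number: 2, unit_length_bp: 4, motif_class: complex,  rm_status: moderate, typical_allele: 21}
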