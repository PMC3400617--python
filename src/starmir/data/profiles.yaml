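# Built-in vector profiles: how a designed insert becomes an
# annealing-ready duplex for one backbone.  All strings are DNA, 5'->3'
# on their own strand.  top_prefix / bottom_prefix / bottom_suffix are
# single-stranded after annealing (restriction-site sticky ends); the
# core (core_prefix + insert body + core_suffix) is fully double-stranded.
# Enzyme names are documentation only - no site inference at runtime.
schema_version: 1
profiles:
  plvx-shRNA2:
    insert_kind: hairpin
    enzymes: [BamHI, EcoRI]
    top_prefix: GATC
    core_prefix: CCC
    core_suffix: TTTTTA
    top_suffix: ""
    bottom_prefix: AATT
    bottom_suffix: ""
    notes: >-
      Pol III shRNA backbone; CCC / TTTTTA flanks follow the pSUPER-style
      insert layout, with the TTTTTA run doubling as the Pol III
      terminator.  Clone between the BamHI and EcoRI sites.
  psiCHECK:
    insert_kind: sensor
    enzymes: [XhoI, NotI]
    top_prefix: TCGA
    core_prefix: C
    core_suffix: ""
    top_suffix: ""
    bottom_prefix: GGCC
    bottom_suffix: ""
    notes: >-
      Renilla-luciferase 3'UTR sensor backbone; insert between the XhoI
      and NotI sites downstream of Renilla luciferase.
  pMIR-Report:
    insert_kind: sensor
    enzymes: [MluI, SacI]
    top_prefix: ""
    core_prefix: C
    core_suffix: ""
    top_suffix: ""
    bottom_prefix: CGCG
    bottom_suffix: AGCT
    notes: >-
      Firefly-luciferase 3'UTR sensor backbone; insert between the MluI
      and SacI sites (SacI leaves a 3' AGCT extension on the bottom
      strand).
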