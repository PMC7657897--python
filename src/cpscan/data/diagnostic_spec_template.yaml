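# Template diagnostic-position specification for CPS classification.
#
# Positions are 1-based on the UNGAPPED anchor sequence named by ref_id
# and must fall inside the glutamine amidotransferase (GAT) domain window
# of interest (residues 278-397 in A. alcalica numbering). The positions
# below are PLACEHOLDERS anchored to the synthetic demonstration
# reference shipped with the package: for real CPS sequences, replace
# ref_id with your A. alcalica anchor and fill the five positions from
# inspection of an annotated GAT-domain alignment (catalytic triad boxed,
# glutamine-binding residues marked).
ref_id: synthetic_ref
triad:
  - {name: Cys, position: 305, expected: C}
  - {name: His, position: 360, expected: H}
  - {name: Glu, position: 362, expected: E}
gln_binding:
  - {name: Gln1, position: 318, expected: S}
  - {name: Gln2, position: 341, expected: N}
window: [278, 397]
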