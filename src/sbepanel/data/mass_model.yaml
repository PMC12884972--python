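# Average-mass constants for SBE/MALDI-TOF oligo arithmetic.
# residue_mass: average masses of internal DNA nucleotide residues (Da).
# end_offset: per-class end-group corrections (Da), calibrated by least
#   squares against the bundled panel's printed mass columns.
# terminator_mass: mass-modified ddNTP increments (Da), reverse-engineered
#   from the bundled panel's UEP/EP mass pairs.
version: 1
residue_mass:
  A: 313.21
  C: 289.18
  G: 329.21
  T: 304.2
end_offset:
  primer: -61.95
  probe: -61.02
terminator_mass:
  A: 327.1
  C: 247.2
  G: 287.2
  T: 271.2
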