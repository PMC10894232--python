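# Linear construct: template linearized upstream of the T7 promoter, no
# canonical terminator.  Tandem-repeats label "R" sits next to the promoter;
# two "1" bits follow; the alternative terminator lies inside the OriC.
# Lengths are transcript coordinates, kbp from the 5' end.
topology: linear
labels:
  - {position_kbp: 0.10, kind: R}
  - {position_kbp: 0.60, kind: BIT1}
  - {position_kbp: 1.20, kind: BIT1}
oric_term_offset_kbp: 1.75
full_length_kbp: 3.19
sim:
  # per-encounter probability that the polymerase terminates at the OriC
  p_term_per_cycle: 0.47
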