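# Circular construct: relaxed plasmid transcribed in a rolling-circle
# manner.  Same within-cycle label layout as the linear construct.  Cycle
# starts are an explicit (not perfectly periodic) list; an OriC-terminated
# product after n cycles has length cycle_starts[n-1] + oric_term_offset,
# i.e. 1.6 / 4.6 / 7.9 / 11.2 / 14.5 kbp for n = 1..5.
topology: circular
labels:
  - {position_kbp: 0.10, kind: R}
  - {position_kbp: 0.60, kind: BIT1}
  - {position_kbp: 1.20, kind: BIT1}
cycle_starts_kbp: [0.0, 3.0, 6.3, 9.6, 12.9]
oric_term_offset_kbp: 1.6
sim:
  p_term_per_cycle: 0.47
  # low stochastic-dissociation hazard; produces the minor populations
  # between successive OriC-terminated lengths
  dissociation_rate_per_kbp: 0.02
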