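# Nominal 3-input NOT/NOR circuit: topology and part parameters.
#
# Promoter strengths are per-DNA values on a 1e-3 RNAP/s scale and are
# multiplied by `scales.promoter` and the plasmid copy number at load, so
# the model works in per-cell total fluxes.  Repressor binding constants
# are on a 1e3 protein scale and multiplied by `scales.binding_constant`
# at load.  Sensor promoter activities are already per-cell totals.
schema_version_rnaps: 1

globals:
  gamma: 0.0067       # mRNA degradation rate, s^-1
  b: 2.0              # uncleaved-mRNA degradation factor
  mu: 0.00026         # dilution rate (cell division), s^-1

scales:
  promoter: 1.0e-3
  binding_constant: 1.0e+3

sensors:
  P_Tac:  {signal: iptg, on_rnaps: 0.045, off_rnaps: 0.0000018, copies: 9}
  P_Tet1: {signal: atc,  on_rnaps: 1.537, off_rnaps: 0.0000266, copies: 9}
  P_Tet2: {signal: atc,  on_rnaps: 0.982, off_rnaps: 0.0000018, copies: 9}
  P_BAD1: {signal: ara,  on_rnaps: 0.043, off_rnaps: 0.0000018, copies: 9}
  P_BAD2: {signal: ara,  on_rnaps: 0.054, off_rnaps: 0.0000037, copies: 9}

promoters:            # y_max (y_min), 1e-3 RNAP/s per DNA
  P_AmeR:   {y_max: 67.0,  y_min: 0.3188, copies: 9}
  P_AmtR:   {y_max: 7.4,   y_min: 0.0002, copies: 9}
  P_BetI:   {y_max: 7.5,   y_min: 0.0152, copies: 9}
  P_BM3R1:  {y_max: 9.3,   y_min: 0.0235, copies: 4}
  P_HlyIIR: {y_max: 49.0,  y_min: 0.0133, copies: 9}
  P_PhlF:   {y_max: 0.8,   y_min: 0.0002, copies: 9}
  P_SrpR:   {y_max: 0.9,   y_min: 0.0002, copies: 9}

repressors:           # k on a 1e3 protein scale; n dimensionless
  P_AmeR:   {k: 0.55, n: 1.1}
  P_AmtR:   {k: 2.24, n: 2.4}
  P_BetI:   {k: 0.12, n: 1.7}
  P_BM3R1:  {k: 0.43, n: 1.3}
  P_HlyIIR: {k: 9.80, n: 1.7}
  P_PhlF:   {k: 0.50, n: 4.2}
  P_SrpR:   {k: 0.06, n: 1.2}

ribozymes:            # cleavage efficiency eta
  bydvJ:   0.90
  riboJ:   0.89
  riboJ10: 0.87
  riboJ51: 0.85
  riboJ53: 0.91
  riboJ54: 0.84
  riboJ57: 0.48
  sarJ:    0.94

rbs:                  # translation efficiency alpha, protein/s per mRNA
  A1: 0.85
  B2: 0.57
  BBa_B0064: 1.22
  E1: 0.04
  F1: 0.16
  H1: 14.5
  P3: 0.43
  S2: 0.07

terminators:          # fold knockdown T
  ECK120029600: 689.0
  ECK120033736: 20.0
  ECK120033737: 124.0
  L3S2P11: 15.0
  L3S2P21: 565.0
  L3S2P55: 29.0
  L3S3P11: 296.0
  L3S3P31: 136.0

# Gates in physical order on the circuit DNA; read-through flows from each
# gate's terminator into the next gate's transcription unit.  The yfp unit
# sits on the separate output plasmid (no read-through in).
gates:
  - {name: phlF,   inputs: [P_SrpR, P_BetI],    output_promoter: P_PhlF,
     ribozyme: riboJ53, rbs: P3, terminator: ECK120033737, readthrough_from: null}
  - {name: srpR,   inputs: [P_BAD1, P_Tet1],    output_promoter: P_SrpR,
     ribozyme: riboJ10, rbs: S2, terminator: ECK120029600, readthrough_from: phlF}
  - {name: bm3R1,  inputs: [P_PhlF, P_HlyIIR],  output_promoter: P_BM3R1,
     ribozyme: sarJ, rbs: B2, terminator: L3S2P11, readthrough_from: srpR}
  - {name: betI,   inputs: [P_AmtR, P_AmeR],    output_promoter: P_BetI,
     ribozyme: riboJ57, rbs: E1, terminator: L3S3P11, readthrough_from: bm3R1}
  - {name: ameR,   inputs: [P_Tet2],            output_promoter: P_AmeR,
     ribozyme: riboJ54, rbs: F1, terminator: L3S3P31, readthrough_from: betI}
  - {name: hlyIIR, inputs: [P_Tac],             output_promoter: P_HlyIIR,
     ribozyme: riboJ51, rbs: H1, terminator: ECK120033736, readthrough_from: ameR}
  - {name: amtR,   inputs: [P_BAD2],            output_promoter: P_AmtR,
     ribozyme: bydvJ, rbs: A1, terminator: L3S2P21, readthrough_from: hlyIIR}
  - {name: yfp,    inputs: [P_BM3R1],           output_promoter: null,
     ribozyme: riboJ, rbs: BBa_B0064, terminator: L3S2P55, readthrough_from: null}

# Designed ON states of the circuit output, as (iptg, atc, ara) bits.
designed_on_states:
  - [1, 0, 0]
  - [1, 1, 1]
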