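# Default parameterization of the firing-rate ring model.
# Every numeric leaf carries a provenance tag:
#   main-text  : part of the modelled experimental setup; fixed
#   calibrated : package default chosen to reproduce the qualitative
#                regime map (no published value available)
# Units: ms, pA, Hz. Intrinsic input per cell class = threshold + background.

model:
  n_populations: {value: 7, provenance: main-text}
  tau_m_ms: {value: 10.0, provenance: main-text}
  gain_slope: {value: 5.33, provenance: main-text}
  periodic: true

cells:
  PYR:
    threshold: {value: 0.0, provenance: calibrated}
    background: {value: 3.0, provenance: main-text}
  PV:
    threshold: {value: -0.5, provenance: calibrated}
    background: {value: 1.5, provenance: calibrated}
  SST:
    threshold: {value: -3.8, provenance: calibrated}
    background: {value: 0.7, provenance: calibrated}
  VIP:
    threshold: {value: 0.0, provenance: calibrated}
    background: {value: 0.6, provenance: calibrated}

connections:
  # intra-population motif: Pyr excites all classes; PV inhibits Pyr and PV;
  # SST inhibits Pyr, PV and VIP; VIP inhibits SST.
  - {pre: PYR, post: PYR, scope: intra,
     weight: {value: 60.0, provenance: calibrated},
     decay_tau_ms: {value: 2.0, provenance: calibrated}}
  - {pre: PYR, post: PV, scope: intra,
     weight: {value: 40.0, provenance: calibrated},
     decay_tau_ms: {value: 2.0, provenance: calibrated}}
  - {pre: PYR, post: SST, scope: intra,
     weight: {value: 400.0, provenance: calibrated},
     decay_tau_ms: {value: 2.0, provenance: calibrated}}
  - {pre: PYR, post: VIP, scope: intra,
     weight: {value: 5.0, provenance: calibrated},
     decay_tau_ms: {value: 2.0, provenance: calibrated}}
  - {pre: PV, post: PYR, scope: intra,
     weight: {value: -20.0, provenance: calibrated},
     decay_tau_ms: {value: 6.0, provenance: calibrated}}
  - {pre: PV, post: PV, scope: intra,
     weight: {value: -15.0, provenance: calibrated},
     decay_tau_ms: {value: 6.0, provenance: calibrated}}
  - {pre: SST, post: PYR, scope: intra,
     weight: {value: -130.0, provenance: calibrated},
     decay_tau_ms: {value: 8.0, provenance: calibrated}}
  - {pre: SST, post: PV, scope: intra,
     weight: {value: -20.0, provenance: calibrated},
     decay_tau_ms: {value: 6.0, provenance: calibrated}}
  - {pre: SST, post: VIP, scope: intra,
     weight: {value: -24.0, provenance: calibrated},
     decay_tau_ms: {value: 30.0, provenance: calibrated}}
  - {pre: VIP, post: SST, scope: intra,
     weight: {value: -320.0, provenance: calibrated},
     decay_tau_ms: {value: 5.0, provenance: calibrated}}
  # inter-population pathways (periodic ring; profile indexed by ring
  # distance 1..3). Pyr->Pyr couples nearest neighbours only; Pyr->SST
  # (the IPPS pathway, the surround-suppression knob) reaches every other
  # population with an exponentially decaying profile.
  - pre: PYR
    post: PYR
    scope: inter
    weight: {value: 15.0, provenance: calibrated}
    decay_tau_ms: {value: 2.0, provenance: calibrated}
    distance_profile:
      - {value: 1.0, provenance: main-text}
      - {value: 0.0, provenance: main-text}
      - {value: 0.0, provenance: main-text}
  - pre: PYR
    post: SST
    scope: inter
    weight: {value: 25.0, provenance: calibrated}
    decay_tau_ms: {value: 2.0, provenance: calibrated}
    distance_profile:
      - {value: 1.0, provenance: calibrated}
      - {value: 0.3679, provenance: calibrated}
      - {value: 0.1353, provenance: calibrated}

protocol:
  amplitude_pA: {value: 0.5, provenance: main-text}
  onset_ms: {value: 500.0, provenance: main-text}
  end_ms: {value: 1000.0, provenance: main-text}
  baseline_window_ms:
    - {value: 200.0, provenance: main-text}
    - {value: 500.0, provenance: main-text}
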