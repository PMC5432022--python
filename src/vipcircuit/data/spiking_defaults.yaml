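# Default parameterization of the spiking column-grid model.
# Provenance tags as in rate_defaults.yaml. Units: ms, mV, pA, pF, Hz.
# The connection probabilities are full-scale pairwise probabilities; at a
# reduced scale they grow inversely (capped at 1) to preserve in-degree.

neuron:
  tau_m_ms: {value: 10.0, provenance: main-text}
  c_m_pF: {value: 206.8, provenance: calibrated}   # fits F-I to 5.33*sqrt(x)
  v_rest_mV: {value: -70.0, provenance: calibrated}
  v_reset_mV: {value: -70.0, provenance: calibrated}
  v_thresh_mV: {value: -50.0, provenance: calibrated}
  t_ref_ms: {value: 2.0, provenance: calibrated}
  tau_syn_ms:  # excitatory, fast inhibition (PV/VIP), slow inhibition (SST)
    - {value: 2.0, provenance: calibrated}
    - {value: 6.0, provenance: calibrated}
    - {value: 10.0, provenance: calibrated}

grid:
  rows: {value: 12, provenance: main-text}
  cols: {value: 16, provenance: main-text}
  cells_per_column_full: {value: 2000, provenance: main-text}

thalamic:
  probability: {value: 0.015, provenance: calibrated}
  weight_pA: {value: 90.0, provenance: calibrated}
  pv_factor: {value: 0.3, provenance: calibrated}
  cells_per_patch: {value: 100, provenance: main-text}

background:
  # single external Poisson fiber per neuron: [rate_Hz, weight_pA]
  PYR:
    rate: {value: 700.0, provenance: calibrated}
    weight: {value: 200.0, provenance: calibrated}
  PV:
    rate: {value: 300.0, provenance: calibrated}
    weight: {value: 150.0, provenance: calibrated}
  SST:
    rate: {value: 1800.0, provenance: calibrated}
    weight: {value: 100.0, provenance: calibrated}
  VIP:
    rate: {value: 16.0, provenance: main-text}   # 20 Hz in the high state
    weight: {value: 6000.0, provenance: calibrated}

connections:
  # intra-column motif
  - {pre: PYR, post: PYR, scope: intra,
     probability: {value: 0.05, provenance: calibrated},
     weight: {value: 15.0, provenance: calibrated}}
  - {pre: PYR, post: PV, scope: intra,
     probability: {value: 0.08, provenance: calibrated},
     weight: {value: 30.0, provenance: calibrated}}
  - {pre: PYR, post: SST, scope: intra,
     probability: {value: 0.08, provenance: calibrated},
     weight: {value: 30.0, provenance: calibrated}}
  - {pre: PYR, post: VIP, scope: intra,
     probability: {value: 0.05, provenance: calibrated},
     weight: {value: 15.0, provenance: calibrated}}
  - {pre: PV, post: PYR, scope: intra,
     probability: {value: 0.10, provenance: calibrated},
     weight: {value: -200.0, provenance: calibrated}}
  - {pre: PV, post: PV, scope: intra,
     probability: {value: 0.10, provenance: calibrated},
     weight: {value: -40.0, provenance: calibrated}}
  - {pre: SST, post: PYR, scope: intra,
     probability: {value: 0.10, provenance: calibrated},
     weight: {value: -250.0, provenance: calibrated}}
  - {pre: SST, post: PV, scope: intra,
     probability: {value: 0.08, provenance: calibrated},
     weight: {value: -300.0, provenance: calibrated}}
  - {pre: SST, post: VIP, scope: intra,
     probability: {value: 0.10, provenance: calibrated},
     weight: {value: -30.0, provenance: calibrated}}
  - {pre: VIP, post: SST, scope: intra,
     probability: {value: 0.12, provenance: calibrated},
     weight: {value: -800.0, provenance: calibrated}}
  # inter-columnar pathways (periodic torus)
  - {pre: PYR, post: PYR, scope: inter,
     reach: {value: 1, provenance: calibrated},
     probability: {value: 0.015, provenance: calibrated},
     weight: {value: 25.0, provenance: calibrated}}
  - {pre: PYR, post: PV, scope: inter,
     reach: {value: 1, provenance: calibrated},
     probability: {value: 0.04, provenance: calibrated},
     weight: {value: 50.0, provenance: calibrated}}
  - {pre: PYR, post: SST, scope: inter,
     reach: {value: 4, provenance: calibrated},
     decay: {value: 1.5, provenance: calibrated},
     probability: {value: 0.04, provenance: calibrated},
     weight: {value: 15.0, provenance: calibrated}}
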