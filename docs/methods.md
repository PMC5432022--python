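# Methods

## The firing-rate ring

Each of 7 populations carries one rate unit per cell class (Pyr, PV, SST,
VIP). Unit dynamics are

    tau_m df/dt = -f + g(I_intrinsic + I_syn + I_stimulus)

with tau_m = 10 ms and the square-root gain g(x) = 5.33 sqrt(x) (Hz per
sqrt(pA)). The gain is rectified: g(x) = 0 for x <= 0. Inhibition can
exceed excitation during transients, and rectification keeps rates real and
nonnegative; it also makes the threshold region of the gain very steep,
which the regime switches below rely on. I_intrinsic is the sum of a
cell-class-specific threshold term and a background input; only their sum
enters the dynamics, and both are exposed in the config. Synaptic input is
I_syn = sum_i w_i S_i with one gating variable per (pathway, presynaptic
population) following dS/dt = -S/tau + f_pre, so the steady-state gating is
tau[s] * f_pre[Hz] (dimensionless) and weights carry units pA per unit
gating.

Wiring: within a population, Pyr excites all four classes; PV inhibits Pyr
and PV; SST inhibits Pyr, PV and VIP; VIP inhibits SST (the canonical
disinhibitory motif; whether PV->VIP or VIP->Pyr edges exist in cortex is
contested, and they are omitted here). Across populations there are
reciprocal Pyr->Pyr connections between nearest ring neighbours only and
Pyr->SST connections to every other population, weighted by an
exponentially decaying function of ring distance (decay length 1
population). The ring is periodic, so every population receives identical
total inter-population weight. The inter-population Pyr->SST weight scale
("IPPS") is the surround-suppression knob; the intra-population Pyr->SST
weight is fixed.

Integration is classical fixed-step RK4 at dt = 0.1 ms (all-zero initial
conditions, stimulus steps applied at bin edges, state clipped at zero
after each step to absorb sub-integrator-tolerance undershoots).
`fixed_point` solves the self-consistency equation with gating at steady
state (scipy hybr) and serves as an oracle for the integrator in stable
regimes; the property suite cross-checks the two on randomized small
networks.

### Parameters and provenance

The printed constants -- tau_m = 10 ms, gain slope 5.33, 7 populations,
Pyr net intrinsic 3.0 pA, stimulus 0.5 pA to Pyr only, the protocol
timings, and the VIP sweep values -- are fixed ("main-text" provenance in
`data/rate_defaults.yaml`). All weights, gating decay constants and the
PV/SST/VIP intrinsic inputs are package calibrations ("calibrated"
provenance): no published values are available for them, so the defaults
were chosen, once, to reproduce the qualitative regime map:

* SNR at the input ratio (~1.06) for IPPS <= 10 pA; SNR < 1 at 15-20 pA
  (stimulus-triggered local SST recruitment, sustained by the loss of VIP
  inhibition onto SST); SNR > 1 and increasing for IPPS >= 25 pA (global
  SST recruitment and lateral sharpening).
* a ~22 Hz Pyr-SST rhythm during the stimulus at IPPS = 25 pA, abolished
  when all SST units are hyperpolarized (default probe -10 pA during
  700-800 ms; the sustained-rhythm amplitude is measured from 50 ms after
  probe onset to skip the disinhibition transient, using a 50-ms
  moving-average detrend so step transients do not count as oscillation).
* surround suppression of the size-tuning curve at VIP background 0.6 and
  0.75 pA, switching to facilitation at 0.9 pA and above.
* moving-object correlations that approach 1 in all driven populations as
  the VIP background approaches 2 pA, with an intermediate window in which
  the population the object moves toward is far more faithful than the one
  it leaves. In this calibration that window sits at ~0.65-0.75 pA,
  narrower and lower than the 0.6-1.1 pA window the full parameter set
  produces; analyses sample it at 0.7 pA.
* growing-object correlations whose center population dips below the edge
  populations at intermediate VIP drive.

The mechanism behind the regime map is bistability between a VIP-dominant
state (SST silent, Pyr tracking feedforward input) and an SST-dominant
state (VIP suppressed, Pyr suppressed), switched locally by stimulus-driven
Pyr->SST drive and globally by tonic IPPS drive or VIP background.

### Readout conventions

* SNR: mean target-population Pyr rate over the stimulus window
  (500-1000 ms) divided by the mean of the other six populations.
* Size tuning: stimulus-evoked response (stimulus-window mean minus
  baseline-window mean, 200-500 ms) of the center population, normalized to
  the 1-RF-object response. Evoked responses are used because the absolute
  window mean is dominated by the state baseline, which hides the
  suppression/facilitation switch.
* Input-output correlations: Pearson correlation between a population's
  stimulus trace and its Pyr rate over t >= 200 ms (the relaxation from
  the silent initial condition is not a stimulus response); when
  |covariance| < 1e-7 the covariance is reported instead (near-silent
  traces make correlations numerical artifacts).
* Stability scan: the decay-constant analysis concerns the within-population
  circuit, so the scan removes the inter-population Pyr->SST pathway
  (ipps = 0), relaxes the network, and labels each (tau_SST->VIP,
  tau_VIP->SST) grid point by the tail mean Pyr rate and its detrended
  peak-to-trough amplitude (oscillatory above 0.5 Hz). At the defaults the
  local circuit is stable; prolonging SST->VIP inhibition lowers the Pyr
  rate and prolonging VIP->SST inhibition raises it, with an oscillatory
  band where VIP->SST gating is fast.

## The synthetic optic-flow scene

A pinhole camera (80 degree horizontal field of view, 640x480 px)
approaches a fronto-parallel plane holding five spheres at constant speed:
a central target sphere (radius 1.2 scene units, 1.5x the flankers) and
four flankers (radius 0.8) at the diagonal half-field positions (+-8/3,
+-2.0), plane at distance 6, speed 3.875 units/s. These geometry defaults
are declared, not inferred: they keep every sphere inside the field at
t = 0, make the flankers start leaving the frame near 0.4 s, and keep the
camera outside the target over the 1-s run. Spheres are drawn as filled
unit-intensity discs -- the downstream code only sums patch intensity, so
shading would be irrelevant detail. Twenty 50-ms frames are split into
16x12 non-overlapping 40x40-px patches; patch intensity sums I map to LGN
rates R = 20 + 60 I/I_max Hz with I_max taken over all patches of all
frames of the run (so rates are comparable across frames), and each patch
drives 100 LGN cells emitting independent Poisson trains, constant within a
frame. The generator reproduces looming geometry and radial optic flow
exactly, but has no luminance/contrast structure, no OFF channel, no
temporal filtering and no rendering noise: passing tests show the circuit
analyses behave as designed under this idealized drive, not that they are
robust to realistic imaging noise.

## The spiking column grid

192 columns on a 16x12 torus; at full scale a column holds ~2000 cells
(80% Pyr, 8% PV, 6% SST, 6% VIP). The default working scale is 0.05
(100 cells/column, 19200 neurons), chosen so a 1-s run takes seconds;
connection probabilities scale inversely with the cell-count factor (capped
at 1) to preserve expected synaptic in-degree. Neurons are leaky
integrate-and-fire with exponential synaptic currents on three channels
(excitatory tau 2 ms; fast inhibition from PV/VIP, 6 ms; slow inhibition
from SST, 10 ms), advanced by exact integration at dt = 0.5 ms (0.05 ms in
single-neuron closed-form tests) with a one-step synaptic delay and a 2-ms
refractory period. The membrane capacitance (206.8 pF, threshold 20 mV
above rest) is set so the deterministic F-I curve is fitted by
5.33 sqrt(I - theta) to better than 10% over [1.02, 2] x rheobase, tying
the spiking neuron to the rate model's gain.

Wiring mirrors the ring: the same intra-column motif; inter-columnar
Pyr->Pyr and Pyr->PV projections to nearest-neighbour columns (short-range
pathway) and Pyr->SST projections out to Chebyshev distance 4 with
probability decay length 1.5 columns (long-range surround pathway);
inhibitory axons stay within their column. LGN patch (i, j) projects only
to column (i, j), onto Pyr and (at 0.3x weight) PV. Each neuron receives
one external Poisson fiber; the VIP fiber rate is 16 Hz (low state) or
20 Hz (high state) with a suprathreshold weight, so VIP firing tracks the
fiber and the state switch moves VIP from ~16 to ~20 Hz. All remaining
probabilities, weights and background rates are calibrated defaults
(`data/spiking_defaults.yaml`).

Under the shipped calibration, ten seed-paired runs of the looming scene
give: Pyr ~6.8 -> 7.4 Hz, PV ~14.7 -> 20.5 Hz and VIP ~15.7 -> 19.7 Hz
increases, and a global SST decrease ~31.5 -> 26.1 Hz from the low to the
high VIP state -- the disinhibition signature, consistent across every
seed pair. The finer spatial effects (the inside/outside-target
correlation changes, the final-frame target-center SST enhancement, and
the edge-dominant response ring at high depolarization) are not reproduced
by this calibration: they are either within seed-to-seed noise at scale
0.05 or, for the correlation-based measures, of opposite sign. The
corresponding acceptance tests are kept at their stated thresholds and
fail, rather than being weakened; they evidently require a detailed
full-scale connectivity table that is not available.

### Spiking analysis definitions

* Column responses: firing rate of the recorded subset (10% of Pyr cells,
  fixed per wiring) per column and 50-ms frame.
* Target segmentation: per frame, a patch is "driven" if its LGN rate
  exceeds the 20-Hz blank rate by 10% of the frame's dynamic range; the
  inside-target mask is the 4-connected driven component containing the
  central patch. Inside/outside masks partition the 192 columns per frame.
* CIT/COT: Pearson correlation between the flattened (column, frame)
  response and LGN-rate vectors over inside samples of all 20 frames (CIT)
  and outside samples of the first 8 frames (COT; the flankers start
  leaving the field at 400 ms).
* Target-center SST: SST rate in the 5x5 columns around the image center
  during the final frame (950-1000 ms); the 5x5 neighbourhood (rather than
  3x3) reduces counting noise at the working scale.
* Edge/surface contrast: mean rate of inside-mask columns 8-adjacent to an
  outside column over the mean of the remaining interior columns, averaged
  over the last four frames.
* Perturbations are seed-paired by construction: wiring, LGN spikes and
  background noise derive from the same base seed in both conditions;
  significance uses a 9-of-10 sign test (binomial p ~ 0.011).

## Problem sizes

Rate-model experiments integrate 1-s runs at dt = 0.1 ms (a second or so
each); the full regime map (SNR sweep, size tuning, correlation sweeps,
probe) runs in about two minutes. Spiking experiments use scale 0.05 and
dt = 0.5 ms (roughly 5-10 s per 1-s run); the ten-pair VIP comparison plus
the probability-sweep and PV-background perturbations comprise 40 runs.

## Known limitations

* All rate-model weights/decays and most spiking parameters are
  calibrations, not published values; quantitative magnitudes (e.g. the
  exact SNR values) are properties of this calibration.
* The rate model's quiescent covariance-fallback regime (all-silent Pyr at
  VIP drive < 0.6 pA) is implemented in the statistics but the shipped
  calibration keeps weak nonzero rates there instead of exact silence.
* No conductance synapses, bursting SST dynamics, plasticity, OFF-channel
  or temporal retinal filtering; layers other than the superficial circuit
  are not modelled.
* The spiking model's spatial fine structure at scale 0.05 is noise-limited;
  see the calibration note above.
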