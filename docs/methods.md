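# Methods

## The control law

The controller is a single causal FIR convolution applied to the recorded
LFP at the control channel's rate (500 Hz by default). The kernel is a
windowed cosine atom

    h[k] = w[k] · cos(2π f₀ (k − c)/fs + φ),    c = (n_taps − 1)/2,

with `w` a Hann window whose support sets the pass-band width (the −3 dB
width of a length-L Hann main lobe is ≈ 1.44·fs/L). Two corrections are
applied after the raw construction:

* the kernel is made exactly zero-mean by subtracting a scaled copy of the
  window (no DC response, so electrode offsets cannot drive the LED);
* for short kernels, the negative-frequency image of the cosine atom leaks
  into the pass band and rotates the realized phase at f₀ (≈17° at 51 taps,
  f₀ = 10 Hz, fs = 500 Hz). The construction phase is therefore iterated —
  a fixed-point update `φ ← φ − (realized − commanded)` — until the response
  phase at f₀, after removing the group-delay term 2π f₀ c/fs, matches the
  command to < 0.001°. The iteration converges in 2–3 steps and preserves
  the identity h(φ+180°) = −h(φ).

Finally the taps are scaled to unit magnitude response at f₀. The causal
kernel delays the signal by c samples; the commanded phase is defined
relative to this delayed signal (no delay compensation is attempted, as in
the fixed-latency firmware being emulated).

The filter output is multiplied by the LFP-to-light gain (light-units per
volt), hard-rectified at zero and saturated at `output_max` (1.0 normalized
light-unit). Rectification rather than offset-and-scale was chosen because
an LED cannot emit negative light and because an always-on offset would
deliver phase-independent drive that obscures the phase effect.

### Two kernel-length defaults

* `design_phase_shift_fir` defaults to **151 taps**: at fs = 500 Hz this
  gives a ≈4.8 Hz pass band with stop-band magnitude < 0.03 an octave on
  either side of f₀ — appropriate for offline spectral work and for
  inspecting kernel shapes.
* The loop engine's `ControllerParams` defaults to **51 taps**: closed-loop
  feedback must arrive well inside the target rhythm's phase-coherence time
  (≈0.4 s for the default plant), and the 151-tap group delay of 0.15 s
  smears the commanded phase enough to halve the achievable suppression.
  50 ms of group delay keeps the loop phase-selective at the cost of a
  wider (~14 Hz) pass band.

Both are configurable; the trade-off (selectivity vs latency) is inherent
to linear-phase FIR control.

## Loop engine

One tick (default 1 ms) performs, in order:

1. advance the plant one step using the stimulation command issued
   `loop_delay_ticks` (default 1) earlier — hardware incurs sub-tick
   processing latency, quantized here to one full tick;
2. push the plant output through the front-end chain (the chain models
   analog circuitry, so it runs at the tick rate) and sample the channel
   scheduled for this tick; with 2 alternating channels each channel sees
   an effective 500 Hz rate;
3. if the sampled channel is channel 0 (the control channel), run one
   controller step; channel 1 is logged but unused (single-input
   single-output control);
4. gate the command by the epoch plan — control epochs and OFF periods
   force stimulation to zero; between controller updates the command is
   held (zero-order hold);
5. append one packet (tick, channel, recorded sample, algorithm output,
   stimulation command, condition, epoch).

The controller history buffer is cleared when a stimulation epoch starts so
conditions are statistically independent. Whether the hardware's record
step precedes or follows actuation within one interrupt is a convention;
the fixed order above is this package's convention and is part of the
reproducibility contract.

Determinism: all randomness derives from the session seed through named
`SeedSequence` substreams (plant process noise, measurement noise) plus the
planner's own seed, all PCG64. The session-log header embeds the fully
resolved configuration; `rerun_from_header` reproduces the packet stream
bit-identically, and the text log round-trips exactly (floats written with
shortest-round-trip `repr`, parsed with round-trip precision).

## Front-end models

* Level shifter: affine map of ±10 V onto 0–3.3 V, saturating at the rails
  (physical circuits clamp rather than error).
* Anti-aliasing filter: 2nd-order Butterworth lowpass, −3 dB at 250 Hz.
  "Cutoff" is interpreted throughout as the −3 dB point of a Butterworth
  prototype; only order and corner frequency are specified by the hardware
  being modelled.
* Recording amplifier: 2nd-order highpass + 1st-order lowpass. The corner
  frequencies are not published for the modelled hardware; defaults of
  1 Hz and 200 Hz bracket the LFP band and are configurable. Gain is
  modelled as unity.
* ADC: uniform mid-rise quantizer, 12 bits over 0–3.3 V by default (a
  typical microcontroller ADC; the true resolution is not published).

Filters are Butterworth designs from `scipy.signal.butter`, applied in
second-order sections; streaming (per-sample, direct-form II transposed)
and batch application are exactly equivalent.

## The synthetic plant

A linear stochastic resonator

    x'' = −ω₀² x − 2ζω₀ x' + k·light(t) + σ ξ(t)

integrated by fixed-step Euler–Maruyama at the loop tick. It is the
minimal model of the phenomenon of interest: a noisy narrow-band LFP whose
band power rises when feedback arrives in phase with velocity (energy
pumped in, effective damping reduced) and falls when it arrives in
anti-phase. Because the drive is rectified, only the fundamental of the
half-wave-rectified feedback (amplitude g·A/2 for pre-rectification
amplitude A) interacts with the resonance; the DC component shifts the
equilibrium (and is removed by the amplifier highpass before the
controller) and harmonics fall outside the band.

Default parameters, with reasoning:

| parameter | default | rationale |
|---|---|---|
| natural_freq_hz | 10 Hz | the oscillation band under study |
| damping_ratio ζ | 0.04 | phase-coherence time 1/(ζω₀) ≈ 0.4 s, long against the 50 ms loop latency — a pronounced, narrow ~10 Hz rhythm |
| noise_sd σ | 20 V/s^1.5 | stationary RMS σ/√(4ζω₀³) ≈ 0.10 V, an LFP-scale signal against the 5 mV measurement noise |
| light_coupling k | 2000 V/s² per light-unit | at unit gain the rectified feedback can shift the effective damping by a multiple of ζ: k·g/(4ω₀²) ≈ 0.13 vs ζ = 0.04, deep in the regime where enhancement saturates and suppression is unambiguous |
| measurement_noise_sd | 5 mV | electrode/amplifier noise floor well below the signal |
| dt_s | 1 ms | the loop tick; the plant is sample-synchronous with the engine |

Closed-form checks used as test oracles: free-decay amplitude over one
damped period `exp(−2πζ/√(1−ζ²))`; stationary standard deviation
`σ/√(4ζω₀³)`; spectral peak at the damped frequency.

What the plant does **not** emulate: opsin kinetics (light acts
instantaneously on acceleration), nonlinear neural-mass dynamics, tissue
light propagation, non-stationarity, artefacts, and multi-channel spatial
structure. Passing closed-loop tests therefore demonstrates that the
*controller and loop* behave as designed against a narrow-band stochastic
oscillation — not that any specific biological tissue would respond
identically.

## Scheduler

Each ON epoch is immediately followed by its OFF/control epoch (controls
interspersed, not pooled at the end). Pseudorandom ordering permutes the
condition list independently within each repetition block using PCG64, so
plans are bit-reproducible across runs and platforms for a fixed seed.
Control epochs carry a reference to the preceding condition for paired
analyses, but the default analysis pools all controls into one reference
spectrum.

## Spectral analysis

Welch averaging with a Hann window, 2 s segments, 50% overlap at 500 Hz
(0.5 Hz resolution — fine enough to resolve the modulation structure around
10 Hz). PSDs are estimated per epoch and averaged within a condition, never
across epoch discontinuities. The first 1 s of every epoch is discarded to
drop filter and loop transients (kernel fill ≤ 0.3 s, plant relaxation
≈ 1/(ζω₀)). The modulation map is the dB ratio of per-condition power to
pooled control power; a ratio (not a difference) keeps the map invariant to
overall signal scale. Band summaries average the power ratio across bins
before converting to dB. The two-cycle tiling duplicates the phase axis
(0–720°) so enhancement/suppression bands that straddle 360° read
continuously.

Session sizes for the packaged statistical checks were fixed by a variance
calculation, not by simulation length available: with 2 s segments, a
10 s epoch yields ~8 segments and a per-bin ratio noise of ~1 dB — adequate
against the >15 dB enhancement and ~2–4 dB suppression of the default
closed loop — while the zero-gain null calibration, which bounds |M| by
3 dB *everywhere* in 5–20 Hz, uses 90 s per condition so the per-bin
estimator noise (~0.5 dB) places 3 dB at ≈6σ.

## Known limitations

* The plant is linear; phenomena that depend on threshold or refractory
  nonlinearities (entrainment plateaus, subharmonics) are out of scope.
* Enhancement at the optimal phase is limited by the output ceiling, so
  its reported dB value measures the saturation regime, not a linear gain.
* Replay mode is open-loop by construction: it reproduces the stimulation
  the hardware *would have* commanded for a recorded LFP, without the
  tissue's reaction to it.
* Hardware timing jitter, serial-protocol framing and multi-headstage
  concurrency are not modelled; the tick is exact by definition.
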