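# Methods

## The communication model

`asbit` simulates an event-driven backscatter sensor network: a transceiver
hub emits a continuous ~915 MHz carrier; each battery-less node announces a
binary event (1 ms bins) by modulating its antenna impedance with its unique
spreading-code identifier, BPSK-chipped at the system clock. The receiver
sees the superposition of all nodes' packets,

    Y(t) = sum_i y_i(t - tau_i) + w(t),

with `w` zero-mean complex additive white Gaussian noise, and recovers every
node's event train by matched filtering against that node's known waveform.

**Identifiers.** Codes are Gold sequences: a preferred pair of maximum-length
sequences (m-stage LFSRs with primitive feedback polynomials, period
2^m − 1) combined by chip-wise XOR at every relative shift gives 2^m + 1
codes whose periodic cross-correlations are three-valued and bounded by
2^((m+1)/2) + 1 for odd m. Each hardware node derives its code from a
13-bit physically-unclonable-function seed selecting the relative shift of
the m = 13 family; of the 8,191-chip period only the first 511 symbols are
transmitted. The shipped polynomial table was validated exhaustively
(full-period check; three-valued cross-correlation check). For length
255 = 2^8 − 1 no preferred pair exists (m divisible by 4); the shipped pair
is best-effort (max |CC| = 63) and the constructor warns.

**Waveforms.** A coded symbol spans three chips of the system clock
(f_clk = 3/T_s, nominally 30 MHz); the chip pattern within a symbol is
S_n · [+1, −1, +1]. The receiver amplifies, downconverts and samples at
30 MSa/s (one sample per chip), leaving

    y(v) = A' · s(v) · [cos(theta_v + phi') − j sin(theta_v + phi')] + w(v),

where `s` is the chip waveform evaluated on the fixed ADC grid with the
node's *actual* clock (free-running oscillators carry a static per-node
offset within ±1,000 ppm; carrier-divided clocks are exact), `A'` the
composite amplitude, and `phi'` the carrier-plus-sampling phase. The
simulator downconverts to a quarter-rate low IF (theta_v = 2π·fs/4·v/fs)
rather than exactly to DC: at zero IF the residual exponential aliases to a
constant, the I and Q branches collapse onto one line, and the
phase-diverse product detector below would be degenerate. The low IF
preserves the equation structure and makes the three-phase combination
exactly phase-invariant.

Drift is modelled as a static per-node frequency offset drawn uniformly
within the bound (supply/temperature drift is slow compared with desk-scale
epochs); the ADC grid is never resampled — the continuous-time chip
waveform is evaluated at grid instants, so drifted packets show the
chip-repeat/chip-skip patterns a real receiver sees.

## Demodulation

Per node, matched filters are synthesized exactly as noise-free
unit-amplitude packets at candidate clock frequencies and template phases.
Per filter the I-branch template is correlated against the received I data
and the Q-branch against the Q data and the two traces multiplied
point-wise; the product vanishes at unlucky phases, but the sum over the
three phase variants obeys the closed form

    sum_psi u_psi w_psi = −(3/2)(P_c Q_s − P_s Q_c),

which is phase-invariant at the matched point (= 1.5·(A'L/2)², L template
samples) and is what the fast path computes with two complex FFT
correlations per clock point (the literal per-filter path is retained and
numerically identical; a conventional coherent-envelope |corr|² combiner is
available as a config switch).

For oscillator nodes the bank spans the drift range — 31 clock points
across ±1,000 ppm × 3 phases = 93 filters in the standard configuration.
Per-clock-point scores combine by **maximum**, not sum: the matched peak
concentrates in the one or two points nearest the node's true offset,
whereas collision cross-talk is clock-insensitive and correlated across the
bank, so summing would amplify it by roughly the bank size (measured ~12×).
A `clock_combine="sum"` switch retains the summed variant.

Divider-clocked nodes need no clock search; the receiver recovers each
node's fixed sub-bin transmit offset once (folding a clip's score trace
modulo the 1 ms bin, with candidate validation over the whole stream) and
then scores only the predicted timeslots — three filters total, and
off-slot false detections are structurally excluded.

**Thresholding.** Detection is two-stage, per node:

1. `k × RMS` of the score trace, adaptive to whatever noise-plus-
   interference level the network presents. `k` was calibrated once on
   pure-noise streams to a false-positive rate of 1e-5 per 1 ms bin for the
   511-symbol code and frozen: continuous mode k = 11.9 (per-bin maximum of
   the correlated trace measured empirically, exponential tail
   extrapolation), slotted mode k = 30.3 (exact bivariate-Gaussian sampling
   of the basis correlations; the slotted RMS uses the lower half of score
   magnitudes so the node's own peaks — up to a quarter of slots at high
   event rates — do not self-mask the threshold).
2. The threshold is then raised to half the node's typical detected peak
   (median of the first-pass scores within a factor four of the largest),
   mirroring per-chip calibration of the receiver: matched peaks sit an
   order of magnitude above collision cross-talk, including the
   high-occupancy bursts that the epoch-wide RMS cannot reject. When the
   chip's amplitude is known to the receiver (the pipeline passes it), an
   absolute floor at half of half the expected clean-peak score guards the
   degenerate case of a node with too few events to estimate its own peak.

Half the expected peak score is the standard half-amplitude decision point
for on-off event detection; the choice interacts with the reported
noise-robustness threshold (see Limitations).

Continuous-mode peaks are deduplicated within one packet duration and
assigned to the 1 ms bin containing the start sample.

## Error accounting and experiments

A missing true event or a false detection counts as one error in its 1 ms
bin; EER = (missed + false) / true events, averaged (unweighted) over the
evaluated target nodes. Networks follow the bench construction: a base
population of 40 target + 38 background nodes with distinct codes, scaled
to the requested size by resampling background nodes with replacement
(replicas keep their source's code, with fresh delays, phases, clock
realizations and independent event trains). Events are homogeneous Poisson
per node, collapsed to at most one per bin (a periodic transmit-every-20 ms
mode reproduces the bench configuration). Default conditions: equal
per-packet SNR (a near-far policy with up to 20 dB spread is available and
dominates error rates when enabled), 50 events/s per node, average SNR
1.7 dB.

Desk-scale problem sizes: epochs of 0.2–1 s with 4–40 evaluated targets
(all targets transmit; only the evaluation subset is demodulated), and for
the costliest continuous-correlation sweeps a proportionally reduced
carrier grid (7.5 MSa/s with 250 events/s per node), which preserves the
two dimensionless quantities the physics depends on — packet occupancy
(events/s × packet samples / sample rate) and per-symbol noise margin —
while cutting the FFT work fourfold.

Measured behaviour at these conditions: the reference 750-node oscillator
and 2,500-node divider networks run at EER ≈ 0–5e-4 ("no measurable
errors" at bench scale); the divider capacity cliff sits between 150k and
200k events/s, so a doubling sweep grid reports 100,000 events/s sustained
below EER 1e-3; the added-noise threshold for a 1,500-node divider network
is ≈ −12.5 to −13 dB; and the code-length sweep under oscillator clocks is
minimized at 511 bits (shorter codes lose noise margin and correlation
headroom; longer codes lose a correlation fraction ≈ L·(residual drift)/2
to chip-slip mismatch against the finite bank, ~22% at length 2047).

## Spike-train decoding harness

The brain-machine-interface application is emulated with a synthetic
velocity-tuned population: 164 neurons at a 9.2 Hz population mean rate
(motor-cortex centre-out statistics), 1 ms Bernoulli bins with
λ_i(t) = b_i + g_i·d_i·v_x(t) clipped at zero; baselines are lognormal
across neurons, tuning is strong (gain comparable to baseline per unit
velocity, random preferred sign), and the cursor velocity is a seeded
band-limited (≤2 Hz) sinusoid mixture, mean-zero, unit variance.
Transmission errors are injected either directly at a controlled spike
error rate (deletion/insertion split configurable) or physically, routing
every spike as a Gold-coded packet through the network simulation.
Preprocessing follows the decoding recipe: optional per-spike ±25 ms
uniform jitter resampled per epoch, non-overlapping 25 ms bins, 650 ms
history windows (26 bins/channel), mean-subtracted velocity targets.
The reference decoder is a ridge regression on flattened count windows
with contiguous 5-fold cross-validation (velocity is smooth; shuffled
splits would leak); scores are per-fold held-out Pearson r, compared across
conditions on Fisher-Z-transformed values with paired two-sided t-tests.
A spiking-network decoder is deliberately out of scope: the robustness
conclusions must not hinge on deep-model training variance.

What the synthetic population does **not** model: correlated trial
structure, non-stationarity, shared latent dynamics, electrode noise, or
multi-dimensional kinematics. Passing tests show the pipeline preserves
and degrades decodable information as specified — not that real-data
correlation values (r ≈ 0.93) are reproduced.

## Numerical choices

- Streams are complex64; templates float32 against such streams; traces
  accumulate in float64. FFT correlation via overlap-save with cached
  stream-segment FFTs (`StreamCorrelator`), identical to direct
  correlation within float round-off (tested).
- Integer-exact code correlations (int64 dot products; FFT path rounded
  back and asserted integral).
- Peak dedup window = one packet duration; the bin of the peak's start
  sample is the event bin; bins straddled by two surviving peaks keep the
  stronger.
- Seeds: every stochastic stage draws from named children of one master
  seed (`numpy.random.SeedSequence`); identical configs are bitwise
  reproducible.
- Degenerate inputs: zero-noise SNR reports +inf; all-zero traces detect
  nothing; empty event files round-trip to empty trains; non-primitive
  LFSR taps raise with the observed period.

## Known limitations

- Simulation-only: waveform distortion, analog front-end imperfections and
  quantization of the measured-chip experiments are absent, so error
  floors here are lower than bench values at identical nominal conditions;
  matches against measured-system error rates are order-of-magnitude by
  construction.
- The noise-robustness threshold and the network capacity pull the
  detection threshold in opposite directions: a lower peak-referenced
  fraction improves the former and inflates the latter. The shipped
  half-peak rule favours capacity fidelity; the measured noise threshold
  (≈ −12.5 to −13 dB for 1,500 divider nodes) is therefore ~4 dB less
  robust than the measured-system reference.
- The divider-vs-oscillator capacity gap here (~1.5–2×) is smaller than
  the bench 3×: per-chip-calibrated thresholds already remove most
  continuous-mode false detections that the discrete-timeslot receiver is
  designed to exclude.
- Slot recovery assumes the node transmits during the calibration clip;
  silent nodes are protected only by the absolute calibrated floor.
- The chip-sampling model is ideal instantaneous sampling at one sample
  per chip; fractional-sample timing offsets alias to integer shifts, so
  sampling-phase effects appear only through clock drift.
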