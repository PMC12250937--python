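# Methods

`spikestream` is a desk-scale, bit-exact software emulation of a real-time
spike-detection datapath of the kind deployed on FPGA-based extracellular
acquisition controllers. This note documents the model, the numerical
conventions, the synthetic data used to exercise it, and the design choices
made where the problem left them open.

## The emulated datapath

An acquisition controller multiplexes up to 128 channels
(8 headstages × 16 channels) over a serial stream: every sampling period it
emits one *frame* introduced by a fixed 64-bit synchronization word
(`docs/format.md`). The processing engine runs three stages per frame:

1. **Decode.** A Moore state machine walks the word stream, recognizes the
   sync word, and attributes each subsequent 16-bit sample to its
   (headstage, channel) slot. Outputs depend only on the machine's state.
   On corruption the decoder re-seeks the sync word byte-by-byte; corrupted
   regions are counted and never emitted.
2. **Filter.** Each channel is highpass-filtered by the same 2nd-order
   Butterworth section (cutoff 300 Hz) in Direct-Form-II, so exactly two
   delay states per channel live in the state store. One shared arithmetic
   path serves all channels in serial slot order — the software image of a
   time-multiplexed hardware datapath with per-channel dual-port RAMs.
3. **Detect.** A spike is declared at step `t` when the filtered sample at
   `t-1` is the lowest of the samples at `t-2, t-1, t` and lies strictly
   below a fixed negative threshold. A detection loads a per-channel
   refractory counter (1.5 ms by default) that is decremented once per
   frame and suppresses all comparisons while active. The event timestamp
   is the index of the peak sample `t-1`.

The engine re-encodes filtered samples plus a spike-flag bitmap in place of
the raw data, mirroring the hardware's bandwidth trade-off.

**Timing model.** The supported (sampling rate, clock) pairings —
30 kHz/84 MHz, 25 kHz/70 MHz, 20 kHz/56 MHz — all give
`clock/fs = 2800` cycles per frame. With the default pipeline depth of 20
cycles per channel slot, 128 channels consume 2560 ≤ 2800 cycles, so the
full channel count is feasible at every rate. The pipeline depth is not a
measured quantity of any physical device; 20 cycles is the value consistent
with a 2800-cycle frame and the latency figures the model reproduces, and
it is configurable. Worst-case detection latency is modeled as
`2/fs + pipeline_cycles/clock` — two samples must be acquired before the
three-sample rule can fire, plus the serial pipeline's processing time
(100.36 µs at 20 kHz).

## Fixed-point conventions

Coefficients are designed in closed form (bilinear transform with prewarp
`K = tan(pi fc/fs)`) and quantized to signed Q2.16 (18-bit, the multiplier
width of the targeted FPGA family):

* rounding: nearest, half toward +infinity;
* the quantized `qb1` is then forced to `-(qb0 + qb2)`, so the feedforward
  taps sum to exactly zero and a DC offset decays to exactly zero output —
  no drift accumulates under quantization;
* one step computes `w = (x << 16) - ((qa1*w1 + qa2*w2) >> 16)` (arithmetic
  shift, i.e. floor), then `y = (qb0*w + qb1*w1 + qb2*w2 + 2^31) >> 32`
  (round-to-nearest back to the sample count scale).

**State width.** The Direct-Form-II internal state of a 300 Hz highpass has
a low-frequency gain of `1/A(1) ≈ 120` at 20 kHz (≈ 265 at 30 kHz): slow
drift of a few hundred microvolts drives `|w|` far beyond what a 32-bit
register at `x << 16` scale can hold, and a saturating 32-bit state would
turn the filter's drift rejection into ±50 µV plateau artifacts. States are
therefore held at the 48-bit accumulator width of the target family's DSP
slices, saturating at ±2^45 — wide enough that even a full-scale DC input
(gain 265 × 32768 ≈ 8.7·10^6 counts) stays linear, while every intermediate
product still fits int64 with both states pinned at the rails. Saturation
is counted and logged, never silent. Rounding-vs-truncation at the output
is a convention (we round); all equivalence claims are internal — the
streaming path and the offline path execute the *same* arithmetic, which is
exactly how the original comparison is designed.

The pure-Python `biquad_step`/`detect_step` are the reference automata; the
numba kernels used by `filter_batch`, `detect_offline` and the engine are
asserted bitwise-equal folds of them in the test suite. Float
double-precision Direct-Form-II (with the *dequantized* coefficients)
serves only as a test oracle for arithmetic error; the fixed-point path
stays within 4 counts of it on noise-like input, and the measured −3 dB
point of the realized filter is within 0.001% of 300 Hz.

**Detector tie-breaks.** "Lowest of three" is implemented as `y1 < y_t`
(strict) and `y1 <= y2` (non-strict): a flat-bottomed trough fires once, at
its last minimum sample. Thresholds are configured in µV and converted once
to integer counts (`round(uV / 0.195)`); the filter has unity passband
gain, so raw and filtered counts share the scale. No detection is possible
during a channel's first two samples. After a detection at step `t`, steps
`t+1 … t+r` are blocked (`r` = refractory in samples), so consecutive event
peaks are at least `r+1` samples apart.

## Synthetic recordings

No public recordings accompany the original system, so validation runs on
synthetic data with known ground truth. Each channel is white Gaussian
noise (σ in µV) plus a slow sinusoidal drift plus spike templates added at
the times of a Poisson process with 2 ms absolute dead time; traces are
quantized at 0.195 µV/count (the LSB scale of the commercial amplifier
family the system uses; configurable). Templates are smooth biphasic
(asymmetric trough + 25% rebound) or triangular waveforms, 0.5–3 ms long,
with the global minimum as the ground-truth alignment point. Per-channel
random substreams are keyed `(seed, headstage, channel)`, so traces are
reproducible and independent of how many channels a spec contains.

The generator dead time (2 ms) deliberately exceeds the 1.5 ms detector
refractory so that streaming-vs-offline comparisons are never confounded by
template overlap inside one refractory window.

What the generator does *not* emulate: correlated or non-Gaussian noise,
spike-shape variability, bursting statistics, electrode geometry, or any
biophysics. Passing the validation protocol therefore demonstrates that
the streaming implementation is *exactly equivalent to the offline
implementation of the same algorithm* under realistic signal amplitudes —
it is not a claim about detection sensitivity on real tissue, which is
governed by the threshold choice as in any hard-threshold method.

## Validation protocol and metrics

The comparison protocol mirrors the original experimental design at desk
scale: 6 synthetic "animals", each 32 channels (2 headstages × 16 channels,
standing in for two implanted probes, labelled RFA/S1), 60 s at 20 kHz
(a scaled-down session; duration is a parameter), three nested thresholds
(−50/−70/−90 µV, with −70/−90/−110 µV selectable), refractory 1.5 ms.
Per-channel parameters are drawn once per master seed: firing rate
U(2, 10) Hz, noise σ U(10, 20) µV, spike peak U(−300, −50) µV, drift
amplitude U(0, 300) µV at U(0.5, 3) Hz, template duration U(0.8, 2) ms.

For every (animal, channel, threshold) cell the streaming engine's event
count `v_o` is compared to the offline reference count `v_e`
(batch-filtering the same quantized trace and folding the same detector):

    delta = (v_o - v_e) / v_e * 100        (percentage error, signed)
    E_acc = 100 - delta                    (percentage accuracy)

plus an exact element-wise comparison of the event index sequences. The
headline aggregate is the unweighted mean over all cells (animals and
channels are balanced, so per-animal and per-cell weighting coincide).
`v_e = 0` with `v_o = 0` is defined as a perfect match (δ = 0); `v_e = 0`
with `v_o > 0` has no finite δ and is flagged and excluded from means with
a warning — the equivalence property means it can only arise from a defect.
Mean accuracy 100%, mean error 0% and index-identity on every channel is a
hard pass/fail property of the implementation, enforced in the test suite
and recomputed by `scripts/acceptance.py`.

## Problem sizes and determinism

Default validation scale: 6 × 32 channels × 60 s × 20 kHz × 3 thresholds
(≈ 230 M channel-samples through the streaming loop twice — engine and
offline arm), about 3 minutes on one CPU core with the numba kernels. All
randomness flows from a single master seed; identical seeds give
byte-identical streams and identical reports.

## Known limitations

* The emulation is cycle-*budgeted*, not cycle-accurate: it checks that the
  serial schedule fits the per-frame cycle budget but does not simulate
  vendor FPGA timing, USB transport, or the stimulation path.
* The published 30 kHz latency figure (66.24 µs) is smaller than two
  sampling periods (66.67 µs) and is not reproducible by any
  "two samples + positive processing time" model; the 20 and 25 kHz figures
  are. The model reports its own consistent values at all three rates and
  the 20 kHz bound is the one treated as normative.
* `frame_index` is informative only; reordered or duplicated indices are
  passed through with a warning rather than re-sorted.
* The word-level FSM view of the decoder requires 16-bit-aligned frames;
  layouts whose spike-flag bitmap has odd length are handled by the byte
  decoder only.
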