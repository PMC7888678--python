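# Methods

## Scope and model summary

This package implements a monaural, deterministic receiver for wideband
biosonar: a single broadcast followed by one or more echoes is converted
into an auditory time–frequency representation, and two quantities are
estimated per echo — the range delay *t* (broadcast-to-echo travel time)
and the glint delay Δt (the time separation of a target's reflecting
points). All computation happens on the *timing of threshold-crossing
events*; amplitudes enter only through the latency they induce. There is
no stochastic component anywhere in the cascade: identical inputs and
configuration give bit-identical outputs.

Out of scope by design: binaural processing, spiking/neuromorphic
dynamics, phase-based sub-microsecond delay hyperacuity, scene acoustics
beyond a single lowpass + attenuation knob (no spreading loss,
atmospheric absorption, beam patterns or Doppler), and interleaved echo
streams from successive broadcasts (sequences must keep echoes separated
by the configured inter-echo interval; overlapping layouts are rejected
at assembly).

## Signal generation

The generator defines the study conditions; its defaults are fixed, not
fitted.

* **Bat chirp**: 3 ms logarithmic downsweep, FM1 55→25 kHz plus an
  independently synthesised FM2 90→50 kHz (the two harmonics of the big
  brown bat call are not exact integer multiples), raised-cosine edges
  over 5% of the duration. Phase is integrated analytically, so
  instantaneous-frequency tests are exact; exactly harmonic components
  are phase-locked to the fundamental.
* **Dolphin click**: a Gabor transient — Gaussian-windowed 95 kHz
  cosine, with the Gaussian width set so the spectral envelope is 20 dB
  down at the farther band edge (40/150 kHz). This gives a ~50 μs,
  three-prominent-wave click; the literature does not prescribe an
  analytic form, so the Gabor choice is ours.
* **Echoes**: one scaled, delayed broadcast replica per glint, summed
  with positive sign by default (a per-glint sign flag exists). Delays
  use FFT phase ramps, so sub-sample separations (9 μs at 500 kHz) are
  exact in band. The default two-glint target uses gain 0.5 per glint:
  constructive interference peaks then sit exactly at broadcast
  amplitude and nulls below it, which is the receiver's reference
  regime (its gain control assumes echoes at or below broadcast scale).
* **Lowpass clutter**: a zero-phase FFT-domain gain ramp — 0 dB below
  the cutoff, `ramp_db_per_khz` above it, capped at `max_db` — because
  it makes the attenuation exactly controllable; the mechanism being
  modelled is the *effect* of off-axis filtering, not a filter topology.
  The seven-echo clutter series uses cutoffs 95→50 kHz in 7.5-kHz steps
  with a 2 dB/kHz ramp capped at 40 dB.
* **Timing layout**: sampling rate 500 kHz, broadcast at 0.5 ms,
  inter-echo separation 5 ms. All times are seconds internally, ms/μs at
  interfaces.

What the generator does **not** emulate: receiver noise, target motion,
reverberation, multi-glint targets with frequency-dependent
reflectivity, and real outer/middle-ear transfer functions. Passing
tests therefore demonstrate the internal consistency of the receiver on
clean, fully-specified inputs — not performance on field recordings.

## Front end

* **Gammatone filterbank**, order 4, ERB 4 kHz, realised as truncated
  FIR impulse responses `t³·exp(−2π·1.019·ERB·t)·cos(2π·cf·t)` (1.5 ms
  long), normalised to unit gain at cf. Because the ERB is constant, the
  group delay (envelope peak at 3/(2π·1.019·ERB) ≈ 117 μs) is identical
  across channels; outputs are advanced by it so event timing is
  unbiased. Dolphin spacing is 1 kHz: 121 channels over 30–150 kHz force
  it.
* **Transduction**: half-wave rectification, then a *causal* 2nd-order
  Butterworth at 10 kHz. Latency is the computational currency, so
  zero-phase smoothing would destroy exactly the physics the model
  trades on. Tiny filter undershoot is clamped to zero. All channels are
  smoothed identically (the receiver does not switch smoothers by cf).
* **Gain normalisation**: the broadcast window's global maximum becomes
  1.0; echoes share the factor. Thresholds are 0.03 + (k−1)(0.95)/9 for
  k = 1..10.
* **Crossing detection**: per event window, channel and level, the first
  upward crossing, linearly interpolated between the bracketing samples.
  The search uses the envelope's running maximum, which guarantees
  crossing times non-decreasing in level. Event windows are derived from
  the sequence annotations (start − 0.25 ms to start + signal duration
  + 1.5 ms, clipped at the next event); they must not overlap.

## Range delay

Dechirping subtracts, per channel and level, the broadcast's crossing
time from the echo's. ALT then *adds* 25 μs per dB of per-channel
attenuation (echo envelope peak vs broadcast envelope peak inside the
event windows, floored at 0 dB) on top of the natural crossing
retardation — the two latency sources are treated as additive.

The range delay is the **leading edge** of the across-channel delay
histogram (bin width 2 μs = one sample; level #1 entries by default,
with an option to pool all levels): the left boundary of the earliest
contiguous bin cluster that by itself holds ≥10% of the histogram mass.
This skips isolated early outliers and discounts — without deleting —
the long rightward tail that ALT builds from the null channels.

Two numerical facts about the leading edge are worth recording:

* An absolute-threshold receiver registers a weaker echo *late*: the
  3% crossing of an envelope whose onset is at half broadcast amplitude
  slips by roughly one envelope cycle of the low channels (~30–50 μs for
  the 3-ms chirp, ~5–15 μs for clicks). The worked-example estimate is
  therefore ≈6.05 ms for a true 6.000 ms delay — receiver behaviour, not
  an estimator bug, and under 1% of the delay.
* ALT moves even the leading cluster by ~25–35 μs, because ERB smoothing
  keeps the interference-peak channels ~1 dB under broadcast scale.

The **low-frequency gate** (bat mode) rejects an echo outright when no
gate-band channel (default 25–30 kHz; configurable down to 23 kHz)
crosses the gate level. The gate level defaults to #2 (13.6%), not #1:
with ~90% overlapping filters, skirt leakage from energy above 35 kHz
still grazes the 3% level in the 30-kHz channel, so level #1 presence
cannot express "these frequencies are absent".

## Glint delay

A channel joins a **void cluster** when (a) its echo envelope peak falls
below half the broadcast's peak in that channel — the stated depth at
which the upper thresholds stop being crossed — judged only where the
broadcast itself crossed ≥4 levels; or (b) its level-1 latency deviates
rightward of the leading edge by more than 3× the across-band MAD (with
a 10 μs floor so flat echoes yield an empty set). Gaps ≤1 kHz inside a
cluster are closed; clusters narrower than 2 channels are dropped as
specks. The null centre is the depth-weighted centroid; bat mode
clusters FM1 (≤50 kHz) and FM2 (>50 kHz) separately and never forms a
spacing across the seam.

A cluster counts as a **wide (lowpass) region** when its *deep core* —
channels below one quarter of broadcast scale — exceeds the widest
registrable null (15 kHz). The outer 0.5-contour is deliberately not
used for this decision: an 18-μs echo's nulls are ~17 kHz wide at that
contour but have <10 kHz cores, whereas a lowpass plateau is deep
throughout.

The **triangular network** registers one apex per adjacent null pair,
quantised to the channel grid and kept within [3 kHz, base] (base
80 kHz bat → glint axis top 12.5 μs; 120 kHz dolphin → 8.3 μs). The
aggregate Δf is the mode of apex spacings (ties resolve toward the raw
mean); fewer than two nulls in a band → no estimate. Wide regions are
tiled with uniformly weighted fill-in candidates at every grid spacing
from 3 kHz up to min(region width, 15 kHz); their reciprocals produce
the broad plateau of spurious glint delays that blurs clutter. Each
glint histogram is also normalised by its area ("image energy"): the
clutter plateau spreads mass and scales down, so the focused echo's
value at the true Δt protrudes.

## Separate glints

Glints separated by more than the integration time (250 μs dolphin,
350 μs bat) no longer interfere; the receiver must report two range
delays and no Δt. Detection is two-step, per channel:

1. **Segmentation** on a heavily smoothed envelope copy (extra causal
   2nd-order Butterworth at 4 kHz — kills the low-channel cycle ripple,
   keeps valleys wider than ~150 μs): two peaks at least one integration
   time apart, the second ≥25% of the first, with the valley below half
   the smaller peak.
2. **Timing** by the first upward crossing, after the valley
   (group-delay-compensated back to the raw envelope), of the lowest
   threshold level that clears the valley — the "shortened window"
   needed to catch the second glint — dechirped against the broadcast's
   crossing at the same level, with the same ALT augmentation.

Channels whose second peak matches a second peak in the *broadcast*
itself (the chirp's other harmonic sweeping through the same band) are
discarded. A second range-delay estimate is emitted only when ≥50% of
the level-1 channels agree; that consensus also pre-empts the
interference pathway (separated half-amplitude echoes hover exactly at
the void criterion's 6-dB boundary and would otherwise sprinkle
spurious nulls). Below consensus, the interference pathway runs as
usual. The level scan matters near the boundary: at 300 μs the
inter-click valley never drops below the 3% level, only below ~14%.

## Problem sizes and determinism

All demonstration runs are desk-scale: the largest (the ten-echo click
series, ~55 ms at 500 kHz through 121 channels) fits in ~2 s and a few
hundred MB; the full test suite runs in well under a minute. The
acceptance script recomputes every headline quantity from scratch in a
few seconds. `--seed` is accepted everywhere for interface uniformity,
but no stage draws random numbers; outputs are bit-identical across
seeds and runs.

## Known limitations

* The leading-edge range delay carries the ~1-cycle onset retardation
  discussed above; applications needing μs-exact absolute delay should
  calibrate it out or use equal-amplitude echoes.
* Glint-delay accuracy is limited by grid quantisation of the null
  spacing (e.g. a true 35-μs separation reads 34.5 μs on the 1-kHz
  dolphin grid) and by centroid bias for nulls truncated at band edges.
* Bat-mode glint estimates below ~70 μs are unreliable: the FM1 band
  (25 kHz wide) cannot hold two nulls spaced >25 kHz, and the FM1/FM2
  seam rule forbids cross-harmonic spacings.
* Echoes more than ~6 dB below broadcast scale everywhere satisfy the
  void criterion in every channel and are effectively treated as
  clutter; the model presumes the animal's gain control keeps echoes of
  interest in the upper half of the dynamic range.
* The wide-region fill-in uses uniform weights; weighting by void depth
  is untested territory.
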