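# scat-biosonar

A Python implementation of the Spectrogram Correlation and Transformation
(SCAT) model of wideband biosonar echo processing — the auditory receiver
by which echolocating big brown bats (*Eptesicus fuscus*) and bottlenose
dolphins (*Tursiops truncatus*) are thought to estimate a target's
**range** from echo delay and its **shape** from the interference spectrum
of its reflecting points (*glints*).

It is intended for computational neuroscientists and sonar engineers who
want a tested, configurable reference receiver: every stage is exposed as
a library function, the whole cascade is wrapped in a
`ScatModel`/`ScatResults` interface, and a `scat` command line drives the
standard demonstration scenarios. No recorded data is needed — the package
synthesises its own bat chirps (FM1 55→25 kHz, FM2 90→50 kHz, 3 ms),
dolphin clicks (~50 μs, 40–150 kHz) and multi-glint echoes with exact
ground truth.

## The model

A broadcast and its echoes pass through:

1. **Gammatone filterbank** — order-4 filters with ERB 4 kHz; bat: 161
   channels, 20–100 kHz at 0.5 kHz; dolphin: 121 channels, 30–150 kHz at
   1 kHz. Heavy overlap (~90%) is a feature, not oversampling.
2. **Transduction** — half-wave rectification + causal 10-kHz lowpass.
   Low channels keep cycle-by-cycle structure; high channels yield smooth
   envelopes.
3. **Thresholding** — gain control scales the broadcast to full scale;
   ten equally spaced levels from 3% to 98% record first-crossing times
   per channel (missing crossings are NaN).
4. **Dechirping** — each echo crossing is referenced to the broadcast
   crossing at the same channel and level, removing the FM sweep's slope.
   The range delay *t* is the leading edge of the across-channel delay
   histogram.
5. **Amplitude–latency trading (ALT)** — every crossing is retarded by
   25 μs per dB of attenuation relative to the broadcast in that channel,
   transposing the echo's spectral profile into timing.
6. **Glint delay** — two glints Δt apart imprint spectral nulls spaced
   Δf = 1/Δt. Nulls are read from threshold voids and retarded latencies;
   a triangular coincidence network registers adjacent-null spacings and
   inverts the dominant spacing: **Δt = 1/Δf**. Glints separated by more
   than the inner-ear integration time (≈250 μs dolphin, ≈350 μs bat)
   instead appear as two separate range delays.
7. **Clutter** — lowpass (off-axis/distant) echoes create a void wider
   than any registrable null; it is tiled with fill-in nulls (spacings
   ~3–15 kHz), blurring the glint image. Normalising each glint histogram
   by its total image energy scales the smeared clutter image down and
   lets the focused target's peak protrude — the model's clutter
   rejection.

## Worked example

```python
from scat import synth, ScatModel

chirp = synth.make_fm_chirp(synth.bat_chirp_spec())          # 2-harmonic FM
target = synth.two_glint_target(6e-3, 100e-6)                # t=6 ms, Δt=100 µs
seq = synth.assemble_sequence(chirp, [target])
res = ScatModel(seq, mode="bat").fit()
print(res.summary())
```

```
SCAT receiver results
======================================================================
mode: bat   fs: 500 kHz   channels: 161   thresholds: 10
ALT: -25 us/dB   triangle base: 80 kHz (axis top 12.5 us)
----------------------------------------------------------------------
event           t (ms)   Dt (us)  Df (kHz)  nulls  chan  flags
echo0            6.050     100.0      10.0      8   154
----------------------------------------------------------------------
t = leading-edge range delay; Dt = glint delay from null spacing Df (Dt = 1/Df)
```

The receiver recovers the range delay (6.050 ms; the ~50 μs excess is the
natural threshold-crossing retardation of an echo whose onset is weaker
than the broadcast), finds 8 interference nulls across FM1 and FM2 with
dominant spacing Δf = 10.0 kHz, and inverts it to the true glint
separation Δt = 100 μs — i.e. a target whose two reflecting points are
1.7 cm apart in air. `res.range_table` / `res.glint_table` give the same
numbers as DataFrames, and `res.plot(outdir)` writes the dechirped
spectrogram plane, range histograms, triangular-network zig-zag and
glint-delay histograms.

From the shell:

```bash
scat synth --preset dolphin-2glint-series --out data/
scat run --input data/dolphin-2glint-series.wav --config data/scat.yaml --out results/
scat demo bat2HFM --out demo/            # also: dolClick, clutterRejection,
                                         # clutterRejection-dolClick
```

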