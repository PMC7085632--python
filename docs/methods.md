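# Methods

This note documents the models behind `deltaz`, the conventions that fix
signs and scale factors, the parameters that matter, and the limits of what
the synthetic experiments can show.

## Signal model

The measurement chain is current excitation / voltage response:
`v(t) = A·|Z(t)|·sin(2πft + φ(t))` for a sinusoidal excitation of amplitude
`A` and frequency `f`, with `|Z(t)| = Z0 + dZ(t)` and the phase in degrees.
The phase origin is the positive-going zero crossing of the excitation, so
the quadrature instants of period `i` are `t = iT + k·T/4`, `k = 0..3`.

* **Dense grid.** Response traces are sampled at `oversample × 4` points per
  carrier period, endpoint-inclusive. Two things follow: quadrature
  instants lie exactly on the grid (no interpolation in the sampler), and
  every block of whole periods has its closing sample, so composite
  trapezoid integration needs no extrapolation. Carrier phase is evaluated
  through the fractional part of `f·t`, which keeps it exact to machine
  precision arbitrarily deep into a trace; naive `sin(2πft)` loses ~6
  digits after 10^5 periods.
* **Biomodulation.** Triangle and sinusoid shapes are zero-mean with *peak*
  deviation `depth` (so the measured-row value of 0.35 Ω peak-to-peak is
  `depth = 0.175`; 0.35/70.39 reproduces the 0.5 % relative-variation
  figure). A linear ramp `a·t` is the analysis waveform for the integration
  detector; `constant` covers degenerate cases.
* **Noise.** Additive white Gaussian at the sampler input, specified by its
  rms in volts and a seed (`numpy.random.default_rng`); identical spec and
  seed reproduce traces bit for bit. The reference disturbance level used
  in the experiments is 0.1 mV rms — the same size as the modulation being
  recovered. Real acquisition noise is neither white nor stationary;
  nothing here models flicker noise, mains pickup or electrode drift.
* **Square carrier.** `sign(sin)` with exact zeros where the crossings land
  on the grid. Off-grid crossings leave an O(grid-step) jitter in
  per-period integrals; the tests bound it explicitly.

## Channel-label convention

For a response `M·sin(θ+φ)`, the per-period channels are

    ReV = (s1−s3)/2 → M·sinφ        ImV = (s2−s4)/2 → M·cosφ

and the recovered phase is `atan2(ReV, ImV)`. The field literature labels
I/Q both ways round; the convention here is fixed by two requirements: the
demodulated phase must equal the configured impedance phase (4.3° in, 4.3°
out), and the single-channel approximation `|V| ≈ in-phase channel` must
carry the `1/cosφ − 1` error law, which holds for the `M·cosφ` channel at
small φ. Every result object carries explicit `channel_labels` recording
this mapping.

## Differential demodulation and restoration

With the carrier DC at zero, `(s2+s4)/2` measures the envelope change
between the 90° and 270° instants: exactly `−T·cosφ·dE/dt/4` per period for
a linear envelope. Restoration multiplies the leaky cumulative sum by
`−4·stride` (stride = carrier periods between records), which telescopes
back to `cosφ·(E(t) − E(0))` with no free gain to tune.

Two difference routes are provided:

* **Within-period** (`demod_differential`): half-period differences, one
  record per acquired period.
* **Consecutive-record** (`demod_two_sample`): only the 0°/90° samples are
  kept and differences are formed between consecutive acquired records,
  rescaled by `−1/(4·stride)` to share the same convention. This is the
  under-sampling route — records may be many periods apart — and the one
  that works under noise (below). The raw `s1`, `s2` streams are also
  exposed, since for a DC-free response they directly read `M·sinφ` and
  `M·cosφ`.

**Why the noisy experiment needs the consecutive-record route.** With white
sampler noise of std σ, a within-period difference carries an O(σ) noise
term but only an O(T·dE/dt) signal term, and the restoration gain `−4·u`
exactly cancels the √n benefit of averaging over n periods: the restored
noise floor is ≈ `2σ√(τf)` *independent of n* (τ = leak time constant,
f = carrier). Coherently averaging the quadrature channels over n periods,
decimating, and differencing consecutive *averaged* records instead makes
the signal term grow with the record spacing while the noise still shrinks
as 1/√n: the restored noise floor becomes `σ√(τf)/n`. For the reference
noisy configuration (σ = 0.1 mV, f = 20 kHz, n = 2000, τ = 2 s) that is
~1e-5 V against a 1e-4 V signal, and the measured restoration correlation
is ≈ 0.99.

**Difference-channel ADC.** Quantization is mid-tread (zero is a code),
rounds half away from zero, saturates at the rails, with one extra code at
+FS keeping the range symmetric. The difference channel's full scale is set
to 8× the rms of the actual difference stream — an auto-ranging
programmable-gain stage in front of the converter — because a fixed scale
cannot serve both the noiseless (|diff| ~ 5e-9 V) and noisy (|diff| ~ 4e-5 V)
streams. The leak time constant defaults to 10 s (well below the ~1 Hz
band) to bound the random walk of noise and quantization residue; the noisy
scenario uses 2 s, trading ~1 % of 1 Hz gain for a 5× lower walk.

## Lock-in full-period integration

Per-block integrals use the composite trapezoid rule on the dense grid
(exact zero for an unmodulated sine period by symmetry; relative error
~5e-5 at 64 samples/period for ramp envelopes, ~2e-7 at 1024 — the oracle
tests pin both). The integral-to-slope conversion divides by `T²/(2π)`
(and by the block's period count), fixed by the requirement that a ramp
`a·t` yields exactly `−a`; the parameter-recovery test verifies this across
four decades of `a` rather than trusting the constant. Slope estimates are
stamped at block centres. `coherent_prefilter` is the matching lock-in
band-pass: a moving average of each quadrature channel over n acquired
periods, with optional decimation to one record per window.

## Derivative detector

The `dZ/dt` stage is a discrete first-order Butterworth high-pass at the
envelope rate (default 1 kSa/s), corner **100 Hz** — above the 0.5–20 Hz
biomodulation band so the band sits on the +20 dB/decade skirt. A 50 Hz
corner was considered and rejected: its measured slope over the upper
decade [2, 20] Hz is 19.36 dB/decade, outside the ±0.5 dB/decade contract
the stage enforces at construction; at 100 Hz the slope is 19.8–20.0
everywhere in the band. The stage is normalized to unit gain at a
reference frequency (1 Hz), so a 1 Hz impedance sinusoid of amplitude X Ω
produces a stage output of amplitude X Ω; the ADC (default 10 bits,
1 mΩ/LSB, ±0.512 Ω) quantizes that signal, and restoration is the leaky
integral times `2π·f_ref`. Filters start from steady state for the initial
input value — the analog stage has been connected long before acquisition,
and cold-starting it would inject a spurious base-impedance step whose
decaying residue masks millohm signals for seconds.

The "resolve" criterion is Pearson correlation ≥ 0.9 between restored and
true modulation over ≥ 10 s, after a 2 s settling skip; with it the
noiseless detector resolves a 1 mΩ, 1 Hz sinusoid at 1 mΩ/LSB (the
quantized ±1-code derivative integrates to a trapezoid that still tracks
the sine). This is a simulation surrogate for a hardware resolution figure:
real front-end noise, ADC nonlinearity and electrode drift are absent. The
second-derivative curve applies the same stage to the quantized output.
Settling is measured as the time after an envelope step until the output
stays within 5 % of its post-step peak excursion; the 0.1 Hz AC-coupling
baseline (time constant 1.59 s) needs ~4.4 s, the derivative stage ~18 ms.

## Scenario problem sizes

Carrier frequencies are reduced where the physics lives entirely in the
envelope domain: the differential-sampling experiment runs a 20 kHz carrier
for 6 s (the source experiment states 1 V, 0.1 mV, 1 Hz but no carrier
frequency), the lock-in experiment 10 kHz for 4 s at 64× oversampling, and
the detector experiments a 4 kHz carrier with the 1 kSa/s envelope stream
(one averaged record per 4 periods, standing in for 1-in-120 at 120 kHz).
The phase-recovery check keeps the full 120 kHz carrier (16 periods
suffice). Every scenario completes in a few seconds on one CPU.

## Known limitations

* No electrode–skin interface model, no Cole-type tissue dispersion, no
  excitation-gating transients; impedance phase is constant per trace
  (an optional sinusoidal phase wobble can emulate the measured 4.27–4.33°
  range, but none of the shipped scenarios uses it).
* Sampler is ideal apart from the finite-aperture window: no jitter,
  droop, or ADC INL/DNL.
* The noise model is white and stationary; passing the noisy acceptance
  checks shows robustness to broadband noise, not to motion artifacts or
  mains interference (the step-artifact scenario covers only the
  settling-time aspect of artifacts).
* Normalization of reported curves is unit-max-abs; mean- and
  centre-value normalization are available where a relative presentation
  is wanted, since both conventions appear in practice.
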