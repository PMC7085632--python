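# deltaz

Simulation and synchronous-detection toolkit for the small pulsatile
component of electrical bioimpedance (EBI).

## The problem

Impedance plethysmography over an artery measures a tissue impedance

    Z(t) = Z0 + dZ(t)

where the static base `Z0` is typically 70–1000 Ω with a phase angle around
4° at a 120 kHz excitation frequency, while the cardiac-pulsation component
`dZ(t)` (~1 Hz) is only 0.1–0.5 % of `Z0` — hundreds of milliohms at most.
Digitizing the full response wastes almost the entire dynamic range of the
ADC on the static part. The detection methods implemented here all use
**differentiation** to remove the base value *before* digitization, so a
coarse, low-power converter can capture the pulsatile waveform. The toolkit
is for instrumentation and signal-processing work: it simulates the whole
measurement chain and quantifies what each detection route can resolve.

## The methods

With sinusoidal excitation `i(t) = A·sin(2πft)` the response is
`v(t) = A·|Z(t)|·sin(2πft + φ)`. Sampling `v` exactly at the excitation
phases 0°/90°/180°/270° (samples `s1..s4` per period) replaces all
trigonometry with sums and differences:

* **Quadrature demodulation** — `DC = (s1+s3)/2`, `ReV = (s1−s3)/2` (carries
  `M·sinφ`), `ImV = (s2−s4)/2` (carries `M·cosφ`), `|V| = √(ReV²+ImV²)`,
  `φ = atan2(ReV, ImV)`. Reduced-sample variants use three or two samples
  per period; for small φ the single in-phase channel approximates `|V|`
  with relative error `1/cosφ − 1` (≈ 0.24 % at 4°).
* **Differential sampling** — with the carrier DC removed, the same sums
  become *half-period differences* of the envelope, a discrete derivative:
  zero for a constant envelope, `−T·cosφ·dE/dt/4` per period for a ramp.
  Only the tiny variation is quantized (on a matching small full scale) and
  digital integration restores the modulation waveform.
* **Lock-in full-period integration** — the integral of the carrier over a
  whole period is zero unless the envelope is changing; for a ramp `a·t` it
  equals `−a·cosφ·T²/(2π)`. Dividing by the scale factor `T²/2π` yields the
  negative envelope slope; integrating the slopes reproduces the (mirrored)
  modulation.
* **Derivative detector** — the demodulated envelope passes through a
  first-order high-pass whose +20 dB/decade skirt spans the biomodulation
  band (0.5–20 Hz), i.e. an analog `dZ/dt` stage. A 10-bit ADC at
  1 mΩ/LSB then resolves milliohm-scale changes, and the stage settles in
  milliseconds after a motion-artifact step where a 0.1 Hz AC-coupling
  filter needs seconds.

## Worked example

```python
import numpy as np
from deltaz import (
    BiomodulationSpec, ExcitationSpec, SamplerConfig,
    make_biomodulation, make_impedance_trace, synthesize_response,
    sample_quadrature, demod_quadrature, rev_approx_error, run_scenario,
)

# pulsatile impedance: 70.39 ohm base, 0.35 ohm p-p triangle, 4.3 deg phase
t = np.linspace(0.0, 0.05, 501)   # 50 ms window, 6000 carrier periods
dZ = make_biomodulation(
    BiomodulationSpec(shape="triangle", mod_frequency=1.0, depth=0.175), t
)
imp = make_impedance_trace(70.39, 4.3, dZ, t)

# excite at 120 kHz and demodulate from the four quadrature samples
exc = ExcitationSpec(frequency=120e3, amplitude=1.0)
resp = synthesize_response(imp, exc, oversample=64)
r = demod_quadrature(sample_quadrature(resp, exc, SamplerConfig()))
print(f"recovered |Z|:   {r.modulus.mean():.4f} ohm")
print(f"recovered phase: {r.phase_deg.mean():.4f} deg")
print(f"ReV-only error at 4 deg: {rev_approx_error(4.0) * 100:.2f} %")

# differential sampling of a 1 V carrier modulated by a 0.1 mV triangle,
# 12-bit conversion of the differences, digital integration
rep = run_scenario("fig11_differential", seed=1)
print(f"restored triangle peak: {rep.metrics['restored_peak_mV_noiseless']:.4f} mV")
print(f"correlation (noiseless / 0.1 mV noise): "
      f"{rep.metrics['corr_noiseless']:.4f} / {rep.metrics['corr_noisy']:.4f}")
```

prints

```
recovered |Z|:   70.4075 ohm
recovered phase: 4.3000 deg
ReV-only error at 4 deg: 0.24 %
restored triangle peak: 0.1000 mV
correlation (noiseless / 0.1 mV noise): 0.9999 / 0.9929
```

The recovered modulus is the per-period mean of `Z0 + dZ(t)` over the 50 ms
window (the triangle is rising there, hence slightly above 70.39 Ω); the
phase comes back exactly. The differential-sampling run shows a 0.1 mV
modulation restored through a 12-bit difference channel, intact even with
noise as large as the modulation itself once the quadrature channels are
coherently averaged before differencing.

## Command line

```sh
deltaz experiment fig13_lockin --out out/        # named end-to-end scenario
deltaz simulate --config cfg.json --out out/     # write a response trace CSV
deltaz demod --method quadrature --in out/trace.csv --exc out/exc.json --out out/
deltaz fixtures --out fixtures/ --seed 1         # deterministic test traces
```

Scenarios: `fig10_error_curve`, `table1_check`, `fig11_differential`,
`fig13_lockin`, `fig15_derivative`, `resolution_sweep`, `settling`. Each
writes a JSON report (`{scenario, seed, params, metrics, artifacts}`).

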