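"""Named end-to-end scenarios, metrics, and seeded fixture generation.

Each scenario reproduces one of the simulation experiments at desk scale:

* ``fig10_error_curve``  — single-channel (ReV-only) modulus error vs phase.
* ``table1_check``       — relative variation and phase recovery from the
  measured-row parameters (Z0 = 70.39 ohm, dZ = 0.35 ohm p-p, phi = 4.3 deg).
* ``fig11_differential`` — 1 V carrier, 0.1 mV / 1 Hz triangle modulation;
  differential sampling, 12-bit conversion of the differences, digital
  integration; with and without 0.1 mV rms added noise (the noisy variant
  adds coherent averaging of the quadrature channels before differencing).
* ``fig13_lockin``       — full-period synchronous integration of a
  triangle-modulated carrier; restoration is the mirrored original.
* ``fig15_derivative``   — the derivative detector's three curves (first and
  second derivative, restored waveform).
* ``resolution_sweep``   — smallest resolvable sinusoidal impedance amplitude
  at 1 mOhm/LSB, 10-bit quantization.
* ``settling``           — derivative stage vs 0.1 Hz AC-coupling settling
  after a x1.5 envelope step.

Scenario carrier frequencies are reduced from the 120 kHz hardware value
where the physics happens entirely in the envelope domain; the choices are
documented in the package's methods note.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import io as _io
from .derivative_detector import (
    DetectorConfig,
    resolution_sweep as _resolution_sweep_op,
    run_detector,
    settling_compare,
)
from .exceptions import ConfigurationError, ValidationError
from .lockin_integrator import (
    coherent_prefilter,
    integrate_full_period,
    restore_modulation,
    slope_from_integral,
)
from .quadrature_demod import (
    demod_differential,
    demod_two_sample,
    restore_from_differences,
    rev_approx_error,
)
from .sampling_adc import ADCConfig, SamplerConfig, quantize, sample_quadrature
from .signal_model import (
    BiomodulationSpec,
    ExcitationSpec,
    ImpedanceTrace,
    NoiseSpec,
    make_biomodulation,
    make_impedance_trace,
    synthesize_response,
)

__all__ = [
    "ExperimentReport",
    "SCENARIOS",
    "run_scenario",
    "estimate_amplitude",
    "generate_fixture",
    "normalize",
    "pearson",
]


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0.0 when either input is constant."""
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def normalize(x: np.ndarray, mode: str = "maxabs") -> np.ndarray:
    """Curve normalization for reports: 'maxabs' (unit peak), 'mean' (divide
    by the mean), or 'center' (divide by the mid-range value)."""
    x = np.asarray(x, dtype=float)
    if mode == "maxabs":
        d = np.max(np.abs(x))
    elif mode == "mean":
        d = np.mean(x)
    elif mode == "center":
        d = 0.5 * (np.max(x) + np.min(x))
    else:
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    return x / d if d != 0 else x.copy()


@dataclass
class ExperimentReport:
    scenario: str
    seed: int
    params: Dict[str, Any]
    metrics: Dict[str, float]
    artifacts: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for k, v in self.metrics.items():
            if not math.isfinite(float(v)):
                raise ValidationError(f"metric {k!r} is not finite: {v!r}")

    def to_dict(self) -> Dict[str, Any]:
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "params": self.params,
            "metrics": {k: float(v) for k, v in self.metrics.items()},
            "artifacts": list(self.artifacts),
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "ExperimentReport":
        return cls(
            scenario=d["scenario"],
            seed=d["seed"],
            params=d["params"],
            metrics=d["metrics"],
            artifacts=list(d.get("artifacts", [])),
        )


def estimate_amplitude(
    restored: np.ndarray,
    mod_frequency: float,
    rate: float,
    waveform: str = "sinusoid",
) -> float:
    """Peak amplitude of a periodic waveform via synchronous projection.

    Projects onto sin/cos at the modulation frequency over an integer number
    of periods (mean-removed, so a constant offset does not bias it).  For a
    triangle the fundamental is 8/pi^2 of the peak, inverted internally.
    """
    x = np.asarray(restored, dtype=float)
    duration = x.size / rate
    n_per = int(np.floor(duration * mod_frequency + 1e-9))
    if n_per < 3:
        raise ValidationError("need at least 3 modulation periods to estimate")
    L = int(round(n_per / mod_frequency * rate))
    x = x[:L] - np.mean(x[:L])
    t = np.arange(L) / rate
    w = 2.0 * np.pi * mod_frequency * t
    c = 2.0 / L * float(x @ np.cos(w))
    s = 2.0 / L * float(x @ np.sin(w))
    fund = math.hypot(c, s)
    if waveform == "triangle":
        return fund * np.pi ** 2 / 8.0
    if waveform == "sinusoid":
        return fund
    raise ConfigurationError(f"unknown waveform {waveform!r}")


# ---------------------------------------------------------------------------
# scenario implementations
# ---------------------------------------------------------------------------

def _triangle_impedance(
    Z0: float, phase_deg: float, depth: float, mod_frequency: float,
    duration: float, env_rate: float = 1000.0, shape: str = "triangle",
) -> ImpedanceTrace:
    time = np.linspace(0.0, duration, int(round(duration * env_rate)) + 1)
    spec = BiomodulationSpec(shape=shape, mod_frequency=mod_frequency, depth=depth)
    return make_impedance_trace(Z0, phase_deg, make_biomodulation(spec, time), time)


def _scn_fig10(seed: int, p: Dict[str, Any], outdir: Optional[Path]) -> ExperimentReport:
    phases = np.arange(0.0, p["max_phase_deg"] + 1e-9, p["step_deg"])
    errors_pct = np.asarray(rev_approx_error(phases)) * 100.0
    artifacts: List[str] = []
    if outdir is not None:
        path = outdir / "fig10_error_curve.csv"
        pd.DataFrame({"phase_deg": phases, "error_pct": errors_pct}).to_csv(
            path, index=False, float_format="%.12g"
        )
        artifacts.append(str(path))
    at4 = float(rev_approx_error(4.0)) * 100.0
    return ExperimentReport(
        scenario="fig10_error_curve",
        seed=seed,
        params=dict(p),
        metrics={
            "error_at_4deg_pct": at4,
            "error_at_4deg_pct_2dp": round(at4, 2),
            "max_error_pct": float(errors_pct[-1]),
        },
        artifacts=artifacts,
    )


def _scn_table1(seed: int, p: Dict[str, Any], outdir: Optional[Path]) -> ExperimentReport:
    Z0, dZ_pp, phase = p["Z0_ohm"], p["dZ_pp_ohm"], p["phase_deg"]
    imp_slow = _triangle_impedance(Z0, phase, dZ_pp / 2.0, p["mod_frequency"], 1.0)
    rel_var_pct = imp_slow.relative_variation * 100.0

    # constant-envelope carrier trace for the phase/modulus recovery
    f = p["carrier_frequency"]
    n_per = int(p["n_periods"])
    time = np.array([0.0, n_per / f])
    imp = make_impedance_trace(Z0, phase, np.zeros(2), time)
    exc = ExcitationSpec(frequency=f, amplitude=1.0)
    resp = synthesize_response(imp, exc, oversample=int(p["oversample"]))
    dr = demod_quadrature_of(resp, exc)
    phase_rec = float(np.mean(dr.phase_deg))
    modulus_rec = float(np.mean(dr.modulus)) / exc.amplitude
    return ExperimentReport(
        scenario="table1_check",
        seed=seed,
        params=dict(p),
        metrics={
            "relative_variation_pct": float(rel_var_pct),
            "relative_variation_pct_1dp": round(float(rel_var_pct), 1),
            "recovered_phase_deg": phase_rec,
            "recovered_phase_deg_1dp": round(phase_rec, 1),
            "recovered_modulus_ohm": modulus_rec,
        },
    )


def demod_quadrature_of(resp, exc):
    """Sample + four-sample demodulation in one step (scenario convenience)."""
    from .quadrature_demod import demod_quadrature

    return demod_quadrature(sample_quadrature(resp, exc, SamplerConfig()))


def _quantize_diff_channel(diff, bits: int, fs_headroom: float = 8.0):
    """Auto-ranged difference-channel ADC: full scale = headroom x rms of the
    difference stream (the programmable-gain stage in front of the converter).
    Returns the ADC config used; the channel is replaced by its dequantized
    values in place."""
    rms = float(np.sqrt(np.mean(diff.dReV ** 2)))
    if rms == 0.0:
        return None
    adc = ADCConfig(bits=bits, full_scale=fs_headroom * rms)
    diff.dReV = quantize(diff.dReV, adc).value.astype(float)
    return adc


def _scn_fig11(seed: int, p: Dict[str, Any], outdir: Optional[Path]) -> ExperimentReport:
    f = p["carrier_frequency"]
    exc = ExcitationSpec(frequency=f, amplitude=p["carrier_amplitude"])
    imp = _triangle_impedance(
        Z0=p["carrier_amplitude"], phase_deg=0.0, depth=p["mod_depth"],
        mod_frequency=p["mod_frequency"], duration=p["duration"],
    )
    mod_spec = BiomodulationSpec(
        shape="triangle", mod_frequency=p["mod_frequency"], depth=p["mod_depth"]
    )
    os_ = int(p["oversample"])

    # --- noiseless: per-period Eq-(6)-style half-period differences ---------
    resp = synthesize_response(imp, exc, oversample=os_)
    qs = sample_quadrature(resp, exc, SamplerConfig())
    diff = demod_differential(qs)
    _quantize_diff_channel(diff, bits=int(p["adc_bits"]))
    restored = restore_from_differences(diff, leak_tc=p["leak_tc_noiseless"])
    t_rec = qs.t[:, 1]
    truth = make_biomodulation(mod_spec, t_rec)
    sel = t_rec >= p["transient_skip"]
    corr_clean = pearson(restored[sel], truth[sel])
    peak = estimate_amplitude(
        restored[sel], p["mod_frequency"], rate=f, waveform="triangle"
    )

    # --- noisy: coherent averaging then consecutive-record differences ------
    noise = NoiseSpec(rms=p["noise_rms"], seed=seed)
    resp_n = synthesize_response(imp, exc, noise=noise, oversample=os_)
    qs_n = sample_quadrature(resp_n, exc, SamplerConfig())
    qs_avg = coherent_prefilter(qs_n, int(p["avg_periods"]), decimate=True)
    diff_n = demod_two_sample(qs_avg)
    _quantize_diff_channel(diff_n, bits=int(p["adc_bits"]))
    restored_n = restore_from_differences(diff_n, leak_tc=p["leak_tc_noisy"])
    t_n = qs_avg.t[:, 1][1:]
    truth_n = make_biomodulation(mod_spec, t_n)
    sel_n = t_n >= p["transient_skip"]
    corr_noisy = pearson(restored_n[sel_n], truth_n[sel_n])

    artifacts: List[str] = []
    if outdir is not None:
        path = outdir / "fig11_restored.csv"
        pd.DataFrame(
            {"t": t_rec[sel], "restored": restored[sel], "truth": truth[sel]}
        ).to_csv(path, index=False, float_format="%.12g")
        artifacts.append(str(path))

    return ExperimentReport(
        scenario="fig11_differential",
        seed=seed,
        params=dict(p),
        metrics={
            "restored_peak_mV_noiseless": peak * 1e3,
            "restored_peak_error_pct": (peak / p["mod_depth"] - 1.0) * 100.0,
            "corr_noiseless": corr_clean,
            "corr_noisy": corr_noisy,
        },
        artifacts=artifacts,
    )


def _scn_fig13(seed: int, p: Dict[str, Any], outdir: Optional[Path]) -> ExperimentReport:
    f = p["carrier_frequency"]
    exc = ExcitationSpec(frequency=f, amplitude=1.0)
    imp = _triangle_impedance(
        Z0=p["Z0"], phase_deg=p["phase_deg"], depth=p["mod_depth"],
        mod_frequency=p["mod_frequency"], duration=p["duration"],
    )
    resp = synthesize_response(imp, exc, oversample=int(p["oversample"]))
    li = integrate_full_period(resp, exc, periods_per_block=1)
    slopes = slope_from_integral(li.integral, exc.period)
    restored = restore_modulation(slopes, exc.period, leak_tc=p["leak_tc"])
    mod_spec = BiomodulationSpec(
        shape="triangle", mod_frequency=p["mod_frequency"], depth=p["mod_depth"]
    )
    truth = make_biomodulation(mod_spec, li.t_center)
    sel = li.t_center >= p["transient_skip"]
    corr_mirror = pearson(restored[sel], -truth[sel])
    slope_true = 4.0 * p["mod_depth"] * p["mod_frequency"]
    cosphi = math.cos(math.radians(p["phase_deg"]))
    slope_ratio = float(np.median(np.abs(slopes[sel]))) / (slope_true * cosphi)

    artifacts: List[str] = []
    if outdir is not None:
        path = outdir / "fig13_lockin.csv"
        _io.write_lockin_csv(li, slopes, restored, path)
        artifacts.append(str(path))
    return ExperimentReport(
        scenario="fig13_lockin",
        seed=seed,
        params=dict(p),
        metrics={
            "corr_restored_vs_mirrored_modulation": corr_mirror,
            "slope_recovery_ratio": slope_ratio,
        },
        artifacts=artifacts,
    )


def _scn_fig15(seed: int, p: Dict[str, Any], outdir: Optional[Path]) -> ExperimentReport:
    cfg = DetectorConfig(adc=ADCConfig.from_lsb(int(p["adc_bits"]), p["adc_lsb_ohm"]))
    exc = ExcitationSpec(frequency=p["carrier_frequency"], amplitude=1.0)
    imp = _triangle_impedance(
        Z0=p["Z0"], phase_deg=0.0, depth=p["mod_depth_ohm"],
        mod_frequency=p["mod_frequency"], duration=p["duration"], shape="sinusoid",
    )
    run = run_detector(imp, exc, cfg, oversample=int(p["oversample"]))
    sel = run.t >= p["transient_skip"]
    corr_restore = pearson(run.restored[sel], run.impedance_true[sel])

    # relative phase of the two derivative streams at the modulation frequency
    def _phase(y: np.ndarray) -> float:
        t = run.t[sel]
        w = 2.0 * np.pi * p["mod_frequency"] * t
        return math.atan2(float(y[sel] @ np.cos(w)), float(y[sel] @ np.sin(w)))

    adv = math.degrees(_phase(run.second_derivative) - _phase(run.first_derivative))
    adv = (adv + 180.0) % 360.0 - 180.0

    artifacts: List[str] = []
    if outdir is not None:
        path = outdir / "fig15_detector.csv"
        pd.DataFrame(
            {
                "t": run.t,
                "first_derivative": run.first_derivative,
                "second_derivative": run.second_derivative,
                "restored": run.restored,
            }
        ).to_csv(path, index=False, float_format="%.12g")
        artifacts.append(str(path))
    return ExperimentReport(
        scenario="fig15_derivative",
        seed=seed,
        params=dict(p),
        metrics={
            "corr_restored_vs_true": corr_restore,
            "second_derivative_phase_advance_deg": adv,
            "saturated_fraction": run.saturated_fraction,
        },
        artifacts=artifacts,
    )


def _scn_resolution(seed: int, p: Dict[str, Any], outdir: Optional[Path]) -> ExperimentReport:
    cfg = DetectorConfig(adc=ADCConfig.from_lsb(int(p["adc_bits"]), p["adc_lsb_ohm"]))
    amplitudes = np.asarray(p["amplitudes_mohm"], dtype=float) * 1e-3
    res = _resolution_sweep_op(
        amplitudes,
        cfg,
        criterion=p["criterion"],
        Z0=p["Z0"],
        mod_frequency=p["mod_frequency"],
        duration=p["duration"],
        carrier_frequency=p["carrier_frequency"],
        oversample=int(p["oversample"]),
    )
    metrics: Dict[str, float] = {}
    for amp, corr in zip(res.amplitudes_ohm, res.correlations):
        metrics[f"corr_at_{amp * 1e3:g}_mohm"] = float(corr)
    if res.smallest_resolved_ohm is None:
        metrics["smallest_resolved_mohm"] = float("inf")  # will fail validation
    else:
        metrics["smallest_resolved_mohm"] = res.smallest_resolved_ohm * 1e3
    return ExperimentReport(
        scenario="resolution_sweep", seed=seed, params=dict(p), metrics=metrics
    )


def _scn_settling(seed: int, p: Dict[str, Any], outdir: Optional[Path]) -> ExperimentReport:
    cfg = DetectorConfig(adc=ADCConfig.from_lsb(int(p["adc_bits"]), p["adc_lsb_ohm"]))
    settle_d, settle_b = settling_compare(
        p["step_scale"],
        cfg,
        hpf_corner=p["hpf_corner"],
        Z0=p["Z0"],
        carrier_frequency=p["carrier_frequency"],
        duration=p["duration"],
        t_step=p["t_step"],
        oversample=int(p["oversample"]),
    )
    return ExperimentReport(
        scenario="settling",
        seed=seed,
        params=dict(p),
        metrics={
            "settle_derivative_s": settle_d,
            "settle_slow_filter_s": settle_b,
        },
    )


_DEFAULTS: Dict[str, Dict[str, Any]] = {
    "fig10_error_curve": {"max_phase_deg": 10.0, "step_deg": 0.5},
    "table1_check": {
        "Z0_ohm": 70.39, "dZ_pp_ohm": 0.35, "phase_deg": 4.3,
        "mod_frequency": 1.0, "carrier_frequency": 120e3,
        "oversample": 64, "n_periods": 16,
    },
    "fig11_differential": {
        "carrier_frequency": 20e3, "carrier_amplitude": 1.0,
        "mod_depth": 1e-4, "mod_frequency": 1.0, "noise_rms": 1e-4,
        "duration": 6.0, "oversample": 16, "adc_bits": 12,
        "avg_periods": 2000, "leak_tc_noiseless": 10.0, "leak_tc_noisy": 2.0,
        "transient_skip": 1.0,
    },
    "fig13_lockin": {
        "carrier_frequency": 10e3, "Z0": 1.0, "phase_deg": 4.3,
        "mod_depth": 0.005, "mod_frequency": 1.0, "duration": 4.0,
        "oversample": 64, "leak_tc": 2.0, "transient_skip": 0.5,
    },
    "fig15_derivative": {
        "carrier_frequency": 4000.0, "Z0": 100.0, "mod_depth_ohm": 0.15,
        "mod_frequency": 1.0, "duration": 10.0, "oversample": 16,
        "adc_bits": 10, "adc_lsb_ohm": 1e-3, "transient_skip": 2.0,
    },
    "resolution_sweep": {
        "carrier_frequency": 4000.0, "Z0": 100.0, "mod_frequency": 1.0,
        "duration": 10.0, "oversample": 16, "adc_bits": 10,
        "adc_lsb_ohm": 1e-3, "criterion": 0.9,
        "amplitudes_mohm": list(range(1, 11)),
    },
    "settling": {
        "carrier_frequency": 4000.0, "Z0": 100.0, "step_scale": 1.5,
        "t_step": 1.0, "duration": 8.0, "oversample": 16,
        "adc_bits": 10, "adc_lsb_ohm": 1e-3, "hpf_corner": 0.1,
    },
}

_RUNNERS = {
    "fig10_error_curve": _scn_fig10,
    "table1_check": _scn_table1,
    "fig11_differential": _scn_fig11,
    "fig13_lockin": _scn_fig13,
    "fig15_derivative": _scn_fig15,
    "resolution_sweep": _scn_resolution,
    "settling": _scn_settling,
}

_DEFAULT_SEEDS = {
    "fig10_error_curve": 0,
    "table1_check": 0,
    "fig11_differential": 11,
    "fig13_lockin": 13,
    "fig15_derivative": 15,
    "resolution_sweep": 5,
    "settling": 7,
}

SCENARIOS = tuple(_RUNNERS)


def run_scenario(
    name: str,
    config: Optional[Dict[str, Any]] = None,
    seed: Optional[int] = None,
    outdir: Optional[Union[str, Path]] = None,
) -> ExperimentReport:
    """Run a named scenario and return its report (optionally writing the
    report JSON and trace artifacts under ``outdir``)."""
    if name not in _RUNNERS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIOS)}"
        )
    params = dict(_DEFAULTS[name])
    if config:
        unknown = set(config) - set(params)
        if unknown:
            raise ConfigurationError(f"unknown config keys for {name}: {sorted(unknown)}")
        params.update(config)
    if seed is None:
        seed = _DEFAULT_SEEDS[name]
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = _RUNNERS[name](int(seed), params, out)
    if out is not None:
        report.to_json(out / f"{name}_report.json")
    return report


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

_FIXTURES = ("fig11", "fig11_noisy", "table1", "fig13")


def generate_fixture(kind: str, seed: int, outdir: Union[str, Path]) -> List[Path]:
    """Write the deterministic CSV trace (+ sidecar JSON) for a named fixture.

    Identical seed and kind reproduce identical bytes; the clean signal
    component does not depend on the seed (only the noise draw does).
    """
    if kind not in _FIXTURES:
        raise ConfigurationError(
            f"unknown fixture {kind!r}; valid kinds: {', '.join(_FIXTURES)}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind in ("fig11", "fig11_noisy"):
        p = _DEFAULTS["fig11_differential"]
        exc = ExcitationSpec(frequency=p["carrier_frequency"], amplitude=1.0)
        imp = _triangle_impedance(
            Z0=1.0, phase_deg=0.0, depth=p["mod_depth"],
            mod_frequency=p["mod_frequency"], duration=0.01,
        )
        noise = NoiseSpec(rms=p["noise_rms"], seed=seed) if kind == "fig11_noisy" else None
        resp = synthesize_response(imp, exc, noise=noise, oversample=16)
        csv_path = outdir / f"{kind}.csv"
        _io.write_trace(resp, csv_path)
        return [csv_path, csv_path.with_suffix(".json")]
    if kind == "table1":
        p = _DEFAULTS["table1_check"]
        imp = _triangle_impedance(
            Z0=p["Z0_ohm"], phase_deg=p["phase_deg"], depth=p["dZ_pp_ohm"] / 2.0,
            mod_frequency=p["mod_frequency"], duration=2.0,
        )
        csv_path = outdir / "table1.csv"
        pd.DataFrame({"time": imp.time, "value": imp.magnitude}).to_csv(
            csv_path, index=False, float_format="%.12g"
        )
        sidecar = {
            "kind": "impedance_magnitude",
            "Z0_ohm": p["Z0_ohm"],
            "phase_deg": p["phase_deg"],
        }
        json_path = csv_path.with_suffix(".json")
        json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return [csv_path, json_path]
    # fig13: short lock-in trace
    p = _DEFAULTS["fig13_lockin"]
    exc = ExcitationSpec(frequency=p["carrier_frequency"], amplitude=1.0)
    imp = _triangle_impedance(
        Z0=p["Z0"], phase_deg=p["phase_deg"], depth=p["mod_depth"],
        mod_frequency=p["mod_frequency"], duration=0.05,
    )
    resp = synthesize_response(imp, exc, oversample=16)
    csv_path = outdir / "fig13.csv"
    _io.write_trace(resp, csv_path)
    return [csv_path, csv_path.with_suffix(".json")]
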