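"""Synthetic excitation, biomodulation, impedance and response-voltage traces.

The measurement situation emulated here is impedance plethysmography: a tissue
impedance ``Z(t) = Z0 + dZ(t)`` is excited with a sinusoidal (or square)
current at a carrier frequency far above the physiological band, and the
response voltage ``v(t) = A * |Z(t)| * sin(2*pi*f*t + phi)`` is what the
detector front ends see.  The pulsatile component ``dZ(t)`` is tiny — a few
tenths of a percent of ``Z0`` at roughly 1 Hz — which is the whole point of
the detection methods in the sibling modules.

Grid conventions
----------------
Dense response grids run at ``oversample * 4`` samples per carrier period and
are endpoint-INCLUSIVE (``n_periods * 4 * oversample + 1`` samples), so that
quadrature instants at excitation phases 0/90/180/270 degrees lie exactly on
the grid and composite integration over whole periods needs no extrapolation.
Carrier phase is computed from the fractional part of ``f * t``; with dyadic
grid steps this keeps the phase exact to machine precision even millions of
periods into a trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as _sps

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "ExcitationSpec",
    "BiomodulationSpec",
    "ImpedanceTrace",
    "ResponseTrace",
    "ResponseMeta",
    "NoiseSpec",
    "make_biomodulation",
    "make_impedance_trace",
    "synthesize_response",
    "add_step_artifact",
]

_WAVEFORMS = ("sinusoid", "square")
_SHAPES = ("triangle", "sinusoid", "ramp", "constant")


@dataclass(frozen=True)
class ExcitationSpec:
    """Excitation current: carrier frequency [Hz], amplitude [relative units],
    waveform.  Phase origin is the positive-going zero crossing of each period."""

    frequency: float = 120e3
    amplitude: float = 1.0
    waveform: str = "sinusoid"

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ConfigurationError("excitation frequency must be > 0")
        if not self.amplitude > 0:
            raise ConfigurationError("excitation amplitude must be > 0")
        if self.waveform not in _WAVEFORMS:
            raise ConfigurationError(
                f"unknown waveform {self.waveform!r}; choose from {_WAVEFORMS}"
            )

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


@dataclass(frozen=True)
class BiomodulationSpec:
    """Shape of the pulsatile deviation dZ(t).

    ``depth`` is the PEAK deviation (not peak-to-peak) for the periodic shapes,
    in the units of the quantity being modulated (ohm for impedance traces,
    volt for voltage-domain experiments).  ``ramp_slope`` [units/s] is used
    only for ``shape='ramp'`` (dZ = a*t)."""

    shape: str = "sinusoid"
    mod_frequency: float = 1.0
    depth: float = 0.0
    ramp_slope: float = 0.0
    phase_offset: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ConfigurationError(
                f"unknown biomodulation shape {self.shape!r}; choose from {_SHAPES}"
            )
        if self.mod_frequency < 0:
            raise ConfigurationError("mod_frequency must be >= 0")
        if self.depth < 0:
            raise ConfigurationError("depth must be >= 0")
        if self.shape == "ramp" and not np.isfinite(self.ramp_slope):
            raise ConfigurationError("ramp shape requires a finite ramp_slope")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise at the sampler input: rms [V] and seed.
    Identical spec + seed reproduces the identical sequence bit for bit."""

    rms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rms < 0:
            raise ConfigurationError("noise rms must be >= 0")


@dataclass
class ImpedanceTrace:
    """Time-indexed impedance magnitude [ohm] and phase [deg] on a uniform grid."""

    time: np.ndarray
    magnitude: np.ndarray
    phase_deg: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValidationError("time grid must be 1-D with at least 2 points")
        steps = np.diff(self.time)
        if not np.all(steps > 0):
            raise ValidationError("time grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise ValidationError("time grid must be uniform")
        if self.magnitude.shape != self.time.shape or self.phase_deg.shape != self.time.shape:
            raise ValidationError("magnitude/phase must match the time grid")
        if not np.all(self.magnitude > 0):
            raise ValidationError("impedance magnitude must be positive everywhere")
        if not np.all(np.isfinite(self.phase_deg)):
            raise ValidationError("impedance phase must be finite")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def relative_variation(self) -> float:
        """(max - min) / mean of the magnitude (dimensionless)."""
        m = self.magnitude
        return float((m.max() - m.min()) / m.mean())


@dataclass(frozen=True)
class ResponseMeta:
    excitation: ExcitationSpec
    oversample: int
    sample_rate: float


@dataclass
class ResponseTrace:
    """Densely sampled response voltage [V]; endpoint-inclusive uniform grid
    covering an integer number of carrier periods."""

    time: np.ndarray
    value: np.ndarray
    meta: ResponseMeta

    @property
    def n_periods(self) -> int:
        return (self.value.size - 1) // (4 * self.meta.oversample)

    @property
    def samples_per_period(self) -> int:
        return 4 * self.meta.oversample


def make_biomodulation(spec: BiomodulationSpec, time: np.ndarray) -> np.ndarray:
    """Evaluate the configured deviation dZ(t) on a uniform time grid.

    Triangle and sinusoid are zero-mean with peak ``depth`` and start at zero
    rising (a quarter period before the first positive peak), so the two
    shapes are phase-aligned.  Ramp is ``ramp_slope * t``; constant is
    ``depth`` everywhere.
    """
    time = np.asarray(time, dtype=float)
    steps = np.diff(time)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
        raise ValidationError("biomodulation time grid must be uniform")
    theta = 2.0 * np.pi * spec.mod_frequency * time + spec.phase_offset
    if spec.shape == "triangle":
        # sawtooth(theta + pi/2, width=0.5) rises through 0 at theta = 0
        return spec.depth * _sps.sawtooth(theta + np.pi / 2.0, width=0.5)
    if spec.shape == "sinusoid":
        return spec.depth * np.sin(theta)
    if spec.shape == "ramp":
        return spec.ramp_slope * time
    if spec.shape == "constant":
        return np.full_like(time, spec.depth)
    raise ConfigurationError(f"unknown biomodulation shape {spec.shape!r}")


def make_impedance_trace(
    Z0: float,
    phase0_deg: float,
    dZ: np.ndarray,
    time: np.ndarray,
) -> ImpedanceTrace:
    """Assemble Z(t) = Z0 + dZ(t) with a constant phase angle [deg]."""
    if not Z0 > 0:
        raise ValidationError("Z0 must be positive")
    dZ = np.asarray(dZ, dtype=float)
    time = np.asarray(time, dtype=float)
    magnitude = Z0 + dZ
    if not np.all(magnitude > 0):
        raise ValidationError("Z0 + dZ must stay positive everywhere")
    phase = np.full_like(time, float(phase0_deg))
    return ImpedanceTrace(time=time, magnitude=magnitude, phase_deg=phase)


def _carrier(exc: ExcitationSpec, time: np.ndarray, phase_rad: np.ndarray) -> np.ndarray:
    # Fractional carrier phase: exact for dyadic grid steps, avoids the
    # catastrophic argument growth of sin(2*pi*f*t) deep into long traces.
    frac = np.mod(exc.frequency * time + phase_rad / (2.0 * np.pi), 1.0)
    if exc.waveform == "sinusoid":
        return np.sin(2.0 * np.pi * frac)
    # Square: +1 on the first half period, -1 on the second, exact 0 at the
    # crossings when they land on the grid (sign convention of sign(sin)).
    out = np.where(frac < 0.5, 1.0, -1.0)
    out[np.mod(2.0 * frac, 1.0) == 0.0] = 0.0
    return out


def synthesize_response(
    imp: ImpedanceTrace,
    exc: ExcitationSpec,
    noise: Optional[NoiseSpec] = None,
    oversample: int = 16,
) -> ResponseTrace:
    """Excite an impedance trace and return the dense response voltage.

    v(t) = amplitude * |Z(t)| * sin(2*pi*f*t + phi(t))   (sinusoid excitation)

    The dense rate is ``oversample * 4 * frequency``; the impedance trace is
    linearly interpolated onto that grid and must cover an integer number of
    carrier periods.  Additive white Gaussian noise is drawn from
    ``numpy.random.default_rng(noise.seed)`` when a NoiseSpec is given.
    """
    if not (isinstance(oversample, (int, np.integer)) and oversample >= 1):
        raise ConfigurationError("oversample must be a positive integer")
    duration = imp.duration
    n_periods_f = duration * exc.frequency
    n_periods = int(round(n_periods_f))
    if n_periods < 1 or abs(n_periods_f - n_periods) > 1e-6 * max(n_periods, 1):
        raise ValidationError(
            "impedance trace must cover an integer number of carrier periods"
        )
    spp = 4 * int(oversample)
    n = n_periods * spp
    dt = 1.0 / (spp * exc.frequency)
    t = imp.time[0] + np.arange(n + 1) * dt
    mag = np.interp(t, imp.time, imp.magnitude)
    phase_rad = np.deg2rad(np.interp(t, imp.time, imp.phase_deg))
    v = exc.amplitude * mag * _carrier(exc, t - imp.time[0], phase_rad)
    if noise is not None and noise.rms > 0:
        rng = np.random.default_rng(noise.seed)
        v = v + rng.normal(0.0, noise.rms, size=v.shape)
    meta = ResponseMeta(excitation=exc, oversample=int(oversample), sample_rate=1.0 / dt)
    return ResponseTrace(time=t, value=v, meta=meta)


def add_step_artifact(resp: ResponseTrace, at: float, scale: float) -> ResponseTrace:
    """Multiply the response by ``scale`` from time ``at`` onward.

    Emulates an abrupt electrode/motion artifact that rescales the envelope;
    used by the settling-time experiments.
    """
    if not (resp.time[0] <= at <= resp.time[-1]):
        raise ValidationError("step time must lie within the trace span")
    value = resp.value.copy()
    value[resp.time >= at] *= scale
    return ResponseTrace(time=resp.time.copy(), value=value, meta=resp.meta)
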