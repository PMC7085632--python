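"""Synchronous sampler, finite-aperture/under-sampling model, and ADC quantizer.

The sampler picks the response voltage exactly at the excitation phases
0/90/180/270 degrees of each carrier period (the quadrature instants).  A
finite aperture replaces the instantaneous pick with the mean of the signal
over a window centred on the instant — physically the integrate-and-settle
behaviour of a real track-and-hold, which doubles as a noise-reducing filter.
Under-sampling keeps only every u-th carrier period; it is valid as long as
the envelope band satisfies Nyquist at the reduced record rate.

The quantizer is mid-tread (zero is a code), rounds half away from zero, and
saturates at the rails; in the analog-difference signal path it digitizes the
per-period differences on a full scale that covers only the variation range,
which is how the methods here buy back dynamic range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .exceptions import ConfigurationError, EffectiveRateWarning, ValidationError
from .signal_model import ExcitationSpec, ResponseTrace

__all__ = [
    "SamplerConfig",
    "QuadratureSamples",
    "ADCConfig",
    "QuantizedResult",
    "sample_quadrature",
    "quantize",
    "analog_difference",
]

_PHASES = (0, 90, 180, 270)

#: Record rate below which a warning is emitted (2 kSa/s is commonly
#: sufficient for cardiovascular signal content).
MIN_RECOMMENDED_RATE = 2000.0


@dataclass(frozen=True)
class SamplerConfig:
    """undersampling_factor u: keep one of every u carrier periods.
    aperture: window length as a fraction of the carrier period in [0, 0.5]
    (0 = instantaneous, 0.5 = half-period integral).
    phase_set: subset of (0, 90, 180, 270) degrees to acquire."""

    undersampling_factor: int = 1
    aperture: float = 0.0
    phase_set: Tuple[int, ...] = _PHASES

    def __post_init__(self) -> None:
        u = self.undersampling_factor
        if not (isinstance(u, (int, np.integer)) and u >= 1):
            raise ConfigurationError("undersampling_factor must be an integer >= 1")
        if not (0.0 <= self.aperture <= 0.5):
            raise ConfigurationError("aperture must lie in [0, 0.5]")
        if not self.phase_set or any(p not in _PHASES for p in self.phase_set):
            raise ConfigurationError(f"phase_set must be a non-empty subset of {_PHASES}")


@dataclass
class QuadratureSamples:
    """Per-acquired-period samples at the quadrature instants.

    ``s`` and ``t`` are (n_records, 4) arrays for phases 0/90/180/270 deg;
    columns of phases not acquired are NaN.  ``stride`` is the number of
    carrier periods between consecutive records (under-sampling and/or
    coherent-average decimation), ``frequency`` the carrier frequency [Hz].
    """

    period_index: np.ndarray
    t: np.ndarray
    s: np.ndarray
    frequency: float
    stride: int = 1

    @property
    def n_records(self) -> int:
        return self.s.shape[0]

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency

    def _col(self, k: int) -> np.ndarray:
        return self.s[:, k]

    @property
    def s1(self) -> np.ndarray:  # 0 deg
        return self._col(0)

    @property
    def s2(self) -> np.ndarray:  # 90 deg
        return self._col(1)

    @property
    def s3(self) -> np.ndarray:  # 180 deg
        return self._col(2)

    @property
    def s4(self) -> np.ndarray:  # 270 deg
        return self._col(3)

    def has_phases(self, phases: Sequence[int]) -> bool:
        cols = [_PHASES.index(p) for p in phases]
        return bool(np.all(np.isfinite(self.s[:, cols])))


@dataclass(frozen=True)
class ADCConfig:
    """Mid-tread quantizer: ``bits`` resolution over the symmetric range
    ±``full_scale``; LSB = 2*full_scale / 2**bits.  Rounds half away from
    zero and saturates at the rails (one extra code at +full_scale keeps the
    range symmetric)."""

    bits: int = 12
    full_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (isinstance(self.bits, (int, np.integer)) and 2 <= self.bits <= 32):
            raise ConfigurationError("bits must be an integer in [2, 32]")
        if not self.full_scale > 0:
            raise ConfigurationError("full_scale must be positive")

    @property
    def lsb(self) -> float:
        return 2.0 * self.full_scale / (2.0 ** self.bits)

    @classmethod
    def from_lsb(cls, bits: int, lsb: float) -> "ADCConfig":
        """Build a config from the quantization step (e.g. 1e-3 ohm/LSB)."""
        return cls(bits=bits, full_scale=lsb * 2.0 ** bits / 2.0)


@dataclass
class QuantizedResult:
    code: np.ndarray
    value: np.ndarray
    saturated: np.ndarray

    @property
    def any_saturated(self) -> bool:
        return bool(np.any(self.saturated))


def sample_quadrature(
    resp: ResponseTrace,
    exc: ExcitationSpec,
    cfg: Optional[SamplerConfig] = None,
) -> QuadratureSamples:
    """Acquire quadrature samples from a dense response trace.

    For ``aperture == 0`` this simply picks grid values (the generator
    guarantees the instants lie on the grid).  For ``aperture = w > 0`` the
    sample is the trapezoid-weighted mean of the trace over a window of
    length ``w*T`` centred on the instant (half-window snapped to the grid);
    the first period is dropped because its 0-degree window would precede
    the trace.  Under-sampling keeps periods 0, u, 2u, ...
    """
    cfg = cfg or SamplerConfig()
    os_ = resp.meta.oversample
    spp = resp.samples_per_period
    n_per = resp.n_periods
    if n_per < 1:
        raise ValidationError("response trace shorter than one carrier period")
    u = cfg.undersampling_factor
    eff_rate = exc.frequency / u
    if eff_rate < MIN_RECOMMENDED_RATE:
        warnings.warn(
            f"effective record rate {eff_rate:.1f} Sa/s is below "
            f"{MIN_RECOMMENDED_RATE:.0f} Sa/s",
            EffectiveRateWarning,
            stacklevel=2,
        )
    offsets = np.array([0, os_, 2 * os_, 3 * os_])
    if cfg.aperture == 0.0:
        periods = np.arange(0, n_per, u)
        idx = periods[:, None] * spp + offsets[None, :]
        s = resp.value[idx]
    else:
        m = int(round(cfg.aperture * spp / 2.0))
        m = max(m, 1)
        first = int(np.ceil(m / spp))  # periods whose 0-deg window precedes t=0
        periods = np.arange(first, n_per, u)
        idx = periods[:, None] * spp + offsets[None, :]
        c = np.concatenate(([0.0], np.cumsum(resp.value)))
        total = c[idx + m + 1] - c[idx - m]
        s = (total - 0.5 * (resp.value[idx - m] + resp.value[idx + m])) / (2.0 * m)
    t = resp.time[periods[:, None] * spp + offsets[None, :]]
    s = np.array(s, dtype=float)
    t = np.array(t, dtype=float)
    for k, p in enumerate(_PHASES):
        if p not in cfg.phase_set:
            s[:, k] = np.nan
            t[:, k] = np.nan
    return QuadratureSamples(
        period_index=periods, t=t, s=s, frequency=exc.frequency, stride=u
    )


def quantize(
    x: Union[float, np.ndarray], adc: ADCConfig
) -> QuantizedResult:
    """Mid-tread quantization with saturation.

    Within ±(full_scale - lsb/2) the dequantized error is at most lsb/2;
    out-of-range inputs clip to the extreme codes and are flagged.
    """
    x = np.asarray(x, dtype=float)
    lsb = adc.lsb
    raw = np.sign(x) * np.floor(np.abs(x) / lsb + 0.5)  # half away from zero
    cmax = 2.0 ** (adc.bits - 1)
    saturated = np.abs(raw) > cmax
    code = np.clip(raw, -cmax, cmax).astype(np.int64)
    value = code * lsb
    return QuantizedResult(code=code, value=value, saturated=saturated)


def analog_difference(
    a: Union[float, np.ndarray], b: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Difference a - b formed in the analog domain, BEFORE quantization.

    The caller then digitizes the result with a difference-channel ADCConfig
    whose full scale covers only the variation range, so the tiny pulsatile
    component uses the converter's whole dynamic range.
    """
    return np.subtract(a, b)
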