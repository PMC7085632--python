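"""Synchronous full-period integration detection.

The integral of a carrier over a whole period is zero while its envelope is
constant; when the envelope ramps with slope ``a`` during the period, the two
half periods no longer cancel and the net integral becomes proportional to
``-a``.  For a sinusoidal carrier

    integral of (E0 + a*t) * sin(2*pi*t/T + phi) over one period
        = -a * cos(phi) * T**2 / (2*pi)

so dividing each per-period integral by the scale factor T**2/(2*pi) yields a
per-period estimate of the NEGATIVE envelope slope.  Integrating those slope
estimates restores the (mirrored) biomodulation waveform.  Coherent averaging
of quadrature channels over n periods is the matching lock-in pre-filter: a
comb/moving-average response that is rock-stable because it is referenced to
the excitation itself, and whose averaged in-phase channel doubles as a base
impedance (electrode quality) indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sps

from .exceptions import DomainError, ValidationError
from .sampling_adc import QuadratureSamples
from .signal_model import ExcitationSpec, ResponseTrace

__all__ = [
    "LockinIntegration",
    "integrate_full_period",
    "slope_from_integral",
    "restore_modulation",
    "coherent_prefilter",
]

#: Per-period integral -> slope conversion for a sinusoid carrier of period T.
def _scale_factor(T: float) -> float:
    return T * T / (2.0 * np.pi)


@dataclass
class LockinIntegration:
    """Per-block integrals of the response: block centres [s], integral values
    [V*s], carrier period [s] and periods per block."""

    t_center: np.ndarray
    integral: np.ndarray
    period_s: float
    periods_per_block: int


def integrate_full_period(
    resp: ResponseTrace,
    exc: ExcitationSpec,
    periods_per_block: int = 1,
) -> LockinIntegration:
    """Composite-trapezoid integral of the response over blocks of whole
    carrier periods (the trace grid is endpoint-inclusive, so every block has
    its closing sample)."""
    if not (isinstance(periods_per_block, (int, np.integer)) and periods_per_block >= 1):
        raise ValidationError("periods_per_block must be an integer >= 1")
    spp = resp.samples_per_period
    B = int(periods_per_block) * spp
    N = resp.value.size - 1
    if N % B != 0:
        raise ValidationError(
            "trace does not cover an integer number of integration blocks"
        )
    dt = 1.0 / resp.meta.sample_rate
    x = resp.value
    # cumulative composite trapezoid, then block differences
    ct = np.concatenate(([0.0], np.cumsum(0.5 * (x[1:] + x[:-1])))) * dt
    edges = np.arange(0, N + 1, B)
    integral = np.diff(ct[edges])
    t_center = 0.5 * (resp.time[edges[:-1]] + resp.time[edges[1:]])
    return LockinIntegration(
        t_center=t_center,
        integral=integral,
        period_s=exc.period,
        periods_per_block=int(periods_per_block),
    )


def slope_from_integral(
    integral: np.ndarray,
    T: float,
    periods_per_block: int = 1,
) -> np.ndarray:
    """Convert per-block integrals to envelope-slope estimates (sign flipped).

    A linear ramp modulation of slope ``a`` yields ``-a`` (times cos(phi) of
    the impedance phase).  Blocks longer than one period average the slope
    over the block, hence the extra division by the period count.
    """
    if not T > 0:
        raise DomainError("carrier period T must be positive")
    return np.asarray(integral, dtype=float) / (_scale_factor(T) * periods_per_block)


def restore_modulation(
    slopes: np.ndarray,
    block_duration: float,
    leak_tc: float = 10.0,
) -> np.ndarray:
    """Leaky time-integration of the slope sequence.

    Since the slopes estimate the NEGATIVE envelope derivative, the restored
    waveform is the mirrored original modulation (restored ~ -(E(t)-E(0))).
    """
    if not block_duration > 0:
        raise ValidationError("block_duration must be positive")
    slopes = np.asarray(slopes, dtype=float)
    alpha = 1.0 if np.isinf(leak_tc) else float(np.exp(-block_duration / leak_tc))
    return _sps.lfilter([1.0], [1.0, -alpha], slopes) * block_duration


def coherent_prefilter(
    qs: QuadratureSamples,
    n_periods: int,
    decimate: bool = False,
) -> QuadratureSamples:
    """Moving average of each quadrature channel over ``n_periods`` records.

    This is the synchronous comb/lock-in band-pass: noise power drops by the
    window length while anything coherent with the carrier passes unchanged.
    With ``decimate=True`` one averaged record is kept per window (record
    stride multiplies by ``n_periods``), which is the form the differential
    under-sampling pipeline consumes.
    """
    if not (isinstance(n_periods, (int, np.integer)) and n_periods >= 1):
        raise ValidationError("n_periods must be an integer >= 1")
    n = int(n_periods)
    if n > qs.n_records:
        raise ValidationError("n_periods exceeds the number of acquired records")
    if n == 1:
        return qs
    K = qs.n_records - n + 1

    def _avg(col: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(col)):
            return np.full(K, np.nan)
        c = np.concatenate(([0.0], np.cumsum(col)))
        return (c[n:] - c[:-n]) / n

    s = np.column_stack([_avg(qs.s[:, k]) for k in range(4)])
    t = np.column_stack([_avg(qs.t[:, k]) for k in range(4)])
    period_index = qs.period_index[:K]
    stride = qs.stride
    if decimate:
        s = s[::n]
        t = t[::n]
        period_index = period_index[::n]
        stride = qs.stride * n
    return QuadratureSamples(
        period_index=period_index,
        t=t,
        s=s,
        frequency=qs.frequency,
        stride=stride,
    )
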