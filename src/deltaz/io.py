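"""CSV/JSON interchange for traces, samples and demodulated outputs.

Trace CSV: two columns ``time,value`` with a header row and 12 significant
digits, plus a sidecar JSON describing the excitation (frequency, amplitude,
waveform) and the dense oversampling factor — enough to reconstruct the
sampling geometry without re-reading the generator config.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .lockin_integrator import LockinIntegration
from .quadrature_demod import DemodResult, DiffDemodResult
from .sampling_adc import QuadratureSamples
from .signal_model import ExcitationSpec, ResponseMeta, ResponseTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_quadrature_csv",
    "write_demod_csv",
    "write_diff_csv",
    "write_lockin_csv",
]

_FLOAT_FMT = "%.12g"


def write_trace(
    resp: ResponseTrace,
    csv_path: Union[str, Path],
    sidecar_path: Optional[Union[str, Path]] = None,
) -> None:
    df = pd.DataFrame({"time": resp.time, "value": resp.value})
    df.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    if sidecar_path is None:
        sidecar_path = Path(csv_path).with_suffix(".json")
    exc = resp.meta.excitation
    sidecar = {
        "frequency": exc.frequency,
        "amplitude": exc.amplitude,
        "waveform": exc.waveform,
        "oversample": resp.meta.oversample,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_trace(
    csv_path: Union[str, Path],
    sidecar_path: Optional[Union[str, Path]] = None,
) -> ResponseTrace:
    if sidecar_path is None:
        sidecar_path = Path(csv_path).with_suffix(".json")
    sidecar = json.loads(Path(sidecar_path).read_text())
    exc = ExcitationSpec(
        frequency=sidecar["frequency"],
        amplitude=sidecar["amplitude"],
        waveform=sidecar["waveform"],
    )
    df = pd.read_csv(csv_path)
    time = df["time"].to_numpy(dtype=float)
    value = df["value"].to_numpy(dtype=float)
    os_ = int(sidecar.get("oversample", 0))
    if os_ < 1:
        duration = time[-1] - time[0]
        n_periods = round(duration * exc.frequency)
        os_, rem = divmod(time.size - 1, 4 * max(n_periods, 1))
        if rem or os_ < 1:
            raise ValidationError("trace length is not an integer number of periods")
    meta = ResponseMeta(
        excitation=exc, oversample=os_, sample_rate=4 * os_ * exc.frequency
    )
    return ResponseTrace(time=time, value=value, meta=meta)


def write_quadrature_csv(qs: QuadratureSamples, path: Union[str, Path]) -> None:
    cols = {"period": qs.period_index}
    for k in range(4):
        cols[f"t{k + 1}"] = qs.t[:, k]
        cols[f"s{k + 1}"] = qs.s[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_demod_csv(result: DemodResult, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "period": result.period_index,
            "DC": result.dc if result.dc is not None else np.nan,
            "ReV": result.ReV,
            "ImV": result.ImV,
            "modulus": result.modulus,
            "phase_deg": result.phase_deg,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_diff_csv(result: DiffDemodResult, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "period": result.period_index,
            "dReV": result.dReV,
            "dImV": result.dImV,
            "restored": result.restored if result.restored is not None else np.nan,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_lockin_csv(
    li: LockinIntegration,
    slopes: np.ndarray,
    restored: np.ndarray,
    path: Union[str, Path],
) -> None:
    df = pd.DataFrame(
        {
            "block": np.arange(li.integral.size),
            "t_center": li.t_center,
            "integral": li.integral,
            "slope": slopes,
            "restored": restored,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
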