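"""CSV/JSON interchange for beat series, waveforms and endpoint tables.

Formats are deliberately plain:

- beat table:      header ``time_s,sbp_mmhg,pi_ms``
- waveform:        header ``time_s,pressure_mmhg`` (uniform grid)
- tidy endpoints:  header ``animal,group,endpoint,value``
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .beats import BeatSeries, PressureWaveform

log = logging.getLogger(__name__)

__all__ = [
    "read_beat_csv",
    "write_beat_csv",
    "read_waveform_csv",
    "write_waveform_csv",
    "read_endpoint_csv",
    "write_endpoint_csv",
    "write_json",
]

BEAT_HEADER = ["time_s", "sbp_mmhg", "pi_ms"]
WAVEFORM_HEADER = ["time_s", "pressure_mmhg"]
ENDPOINT_HEADER = ["animal", "group", "endpoint", "value"]


def _check_header(df: pd.DataFrame, required: list[str], path: Path, optional=()) -> None:
    missing = [c for c in required if c not in df.columns]
    extra = [c for c in df.columns if c not in required and c not in optional]
    if missing or extra:
        raise ValueError(
            f"{path}: expected columns {required} (got {list(df.columns)})"
        )


def write_beat_csv(beats: BeatSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": beats.t, "sbp_mmhg": beats.sbp, "pi_ms": beats.pi}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_beat_csv(path: str | Path) -> BeatSeries:
    """Read a beat table; recompute pulse intervals if the column is absent.

    Non-increasing beat times are a hard error naming the offending row
    (1-based data rows, header excluded).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, BEAT_HEADER[:2], path, optional=("pi_ms",))
    t = df["time_s"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-increasing time_s at data row {int(bad[0]) + 2}"
        )
    if "pi_ms" in df.columns:
        pi = df["pi_ms"].to_numpy(float)
        return BeatSeries(t=t, sbp=df["sbp_mmhg"].to_numpy(float), pi=pi)
    log.info("%s: pi_ms column missing; recomputing pulse intervals from time_s", path)
    pi = np.diff(t) * 1000.0
    return BeatSeries(t=t[1:], sbp=df["sbp_mmhg"].to_numpy(float)[1:], pi=pi)


def write_waveform_csv(w: PressureWaveform, path: str | Path) -> None:
    pd.DataFrame({"time_s": w.times, "pressure_mmhg": w.samples}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_waveform_csv(path: str | Path) -> PressureWaveform:
    """Read a waveform CSV; the sampling rate is inferred from the time grid."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, WAVEFORM_HEADER, path)
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: waveform needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.nonzero(dt <= 0)[0][0]) + 2
        raise ValueError(f"{path}: non-increasing time_s at data row {row}")
    if np.ptp(dt) > 1e-6 * dt.mean():
        raise ValueError(f"{path}: time grid is not uniform")
    return PressureWaveform(
        samples=df["pressure_mmhg"].to_numpy(float),
        fs=1.0 / float(dt.mean()),
        start_time=float(t[0]),
    )


def write_endpoint_csv(df: pd.DataFrame, path: str | Path) -> None:
    if list(df.columns) != ENDPOINT_HEADER:
        raise ValueError(f"endpoint table must have columns {ENDPOINT_HEADER}")
    df.to_csv(path, index=False, float_format="%.10g")


def read_endpoint_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, ENDPOINT_HEADER, path)
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
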