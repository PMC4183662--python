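"""Calibrated audio ingest: WAV reading and conversion to sound pressure.

A measurement chain for underwater sound consists of a hydrophone (volts per
pascal), an amplifier (dimensionless voltage gain) and a recorder whose
digital full scale corresponds to a known input voltage.  A raw sample
normalised to [-1, 1] therefore maps to pressure as

    p [Pa] = raw * adc_fullscale_volts / (hydrophone_sensitivity * amplifier_gain)

Absolute dB values depend on every element of this chain.  The hydrophone
sensitivity is typically known from its calibration sheet (e.g. 47.7 uV/Pa
for a B&K 8104); amplifier gain and recorder full scale must be supplied by
the user.  The defaults (gain 1.0, full scale 1.0 V) are placeholders: with
them the *relative* structure of a recording is correct but absolute levels
are only meaningful once the true chain is configured.
"""

from __future__ import annotations

import json
import math
import wave as _wave
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.io import wavfile as _wavfile

__all__ = [
    "CalibrationChain",
    "PressureSeries",
    "read_recording",
    "apply_calibration",
    "write_table",
    "write_wav",
    "round_db",
]

#: sentinel level (dB) for zero-energy input — log of zero pressure
DB_SENTINEL = -math.inf


def round_db(x: float) -> int:
    """Round a level to integer dB, half away from zero (report convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CalibrationChain:
    """Hydrophone + amplifier + ADC chain mapping digital full scale to pascals.

    Parameters
    ----------
    hydrophone_sensitivity_v_per_pa:
        Hydrophone voltage sensitivity in V/Pa (e.g. ``47.7e-6``).
    amplifier_gain:
        Output volts per input volt of the conditioning amplifier.
    adc_fullscale_volts:
        Input voltage corresponding to digital full scale (+/-1.0).
    """

    hydrophone_sensitivity_v_per_pa: float = 47.7e-6
    amplifier_gain: float = 1.0
    adc_fullscale_volts: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "hydrophone_sensitivity_v_per_pa",
            "amplifier_gain",
            "adc_fullscale_volts",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def pa_per_fullscale(self) -> float:
        """Pascals represented by a digital full-scale sample."""
        return self.adc_fullscale_volts / (
            self.hydrophone_sensitivity_v_per_pa * self.amplifier_gain
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "CalibrationChain":
        """Load a chain from a YAML or JSON config file."""
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"calibration config not found: {path}")
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, Mapping):
            raise ValueError(f"calibration config {path} is not a mapping")
        known = {
            "hydrophone_sensitivity_v_per_pa",
            "amplifier_gain",
            "adc_fullscale_volts",
        }
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown calibration keys in {path}: {sorted(unknown)}")
        return cls(**cfg)


@dataclass
class PressureSeries:
    """Uniformly sampled sound pressure in pascals.

    Attributes
    ----------
    samples:
        Pressure samples in Pa (1-D float array).
    sample_rate:
        Sampling rate in Hz.
    t0:
        Time of the first sample in seconds (default 0, file start).
    """

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("PressureSeries requires a 1-D sample array")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("pressure samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n_samples / sample_rate)."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


_PCM_NORM = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,  # scipy upshifts 24-bit PCM into int32
    np.dtype(np.uint8): None,  # handled separately (offset binary)
}


def _normalize_raw(data: np.ndarray) -> np.ndarray:
    """Map integer/float WAV samples to [-1, 1] with full scale at +/-1."""
    if data.dtype.kind == "f":
        return data.astype(np.float64)
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    norm = _PCM_NORM.get(data.dtype)
    if norm is None:
        raise ValueError(f"unsupported WAV sample format: {data.dtype}")
    return data.astype(np.float64) / norm


def read_recording(path: str | Path, chain: CalibrationChain) -> PressureSeries:
    """Read a mono WAV file and convert samples to calibrated pressure.

    Accepts PCM 8/16/24/32-bit and IEEE float WAV.  Digital full scale maps
    to +/-1.0 before the calibration chain is applied.

    Raises
    ------
    ValueError
        If the file has more than one channel.
    OSError
        If the file is unreadable or its header is truncated.
    """
    path = Path(path)
    try:
        sample_rate, data = _wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises assorted errors on bad headers
        raise OSError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    raw = _normalize_raw(data)
    return PressureSeries(raw * chain.pa_per_fullscale, float(sample_rate))


def apply_calibration(
    raw: Sequence[float] | np.ndarray,
    chain: CalibrationChain,
    sample_rate: float = 44100.0,
    t0: float = 0.0,
) -> PressureSeries:
    """Scale normalised samples in [-1, 1] to pascals (linear, invertible)."""
    raw = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw samples must be finite")
    return PressureSeries(raw * chain.pa_per_fullscale, sample_rate, t0)


def write_wav(path: str | Path, series: PressureSeries, chain: CalibrationChain | None = None) -> None:
    """Write a PressureSeries as a mono float32 WAV.

    With a calibration chain the inverse scaling (Pa -> normalised raw) is
    applied so that ``read_recording`` round-trips; without one the samples
    are written as pascals directly (float WAV has no hard full scale).
    """
    x = series.samples
    if chain is not None:
        x = x / chain.pa_per_fullscale
    _wavfile.write(Path(path), int(round(series.sample_rate)), x.astype(np.float32))


def write_24bit_wav(path: str | Path, raw: np.ndarray, sample_rate: int) -> None:
    """Write normalised samples in [-1, 1] as 24-bit PCM (test/interchange aid)."""
    raw = np.asarray(raw, dtype=np.float64)
    q = np.clip(np.round(raw * (2**23 - 1)), -(2**23), 2**23 - 1).astype(np.int64)
    with _wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(3)
        w.setframerate(sample_rate)
        w.writeframes(b"".join(int(v).to_bytes(3, "little", signed=True) for v in q))


def _prepare_rows(rows: Iterable[Mapping]) -> list[dict]:
    """Materialise records, adding integer-rounded companions for dB fields."""
    out = []
    for row in rows:
        d = dict(row)
        for key in list(d):
            if key.endswith("_db") or "_db_re_" in key:
                v = d[key]
                if isinstance(v, (int, float)) and math.isfinite(v):
                    d[key + "_int"] = round_db(v)
        out.append(d)
    return out


def write_table(
    rows: Iterable[Mapping],
    path: str | Path,
    format: str = "csv",
    add_rounded_db: bool = True,
) -> None:
    """Write homogeneous records to CSV or JSON.

    dB-valued fields (names ending in ``_db``) are written at full precision
    and, when ``add_rounded_db`` is set, duplicated as integer-rounded
    ``*_db_int`` columns for parity with integer-dB report tables.
    """
    import pandas as pd

    rows = _prepare_rows(rows) if add_rounded_db else [dict(r) for r in rows]
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(rows)
        df.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2, default=float)
    else:
        raise ValueError(f"unsupported table format: {format!r}")
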