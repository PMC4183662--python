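"""Sound-exposure metrics for impulsive pile-driving noise.

All metrics follow the standard underwater-acoustics definitions with
reference pressure 1 uPa:

* SPL         10*log10(mean p^2 / pref^2)            dB re 1 uPa
* SPL_peak    20*log10(max |p| / pref)               dB re 1 uPa
* SEL         10*log10(integral p^2 dt / pref^2 s)   dB re 1 uPa^2 s
* SEL_ss      SEL over one detected strike window
* SEL_cum     decibel (energy) sum of SEL_ss over all strikes; inter-strike
              quiet time is excluded by construction
* SEL_cum,p   practical cumulative level: mean SEL_ss + 10*log10(N)

The practical form is exact when every strike carries the same energy and
is the standard way exposure studies extrapolate a cumulative level from a
mean single-strike level and a hammer strike count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .calibration import DB_SENTINEL, PressureSeries, round_db
from .detection import P_REF_PA, StrikeEvent, extract_event_segment
from .bands import ThirdOctaveSpectrum, dominant_band

__all__ = [
    "ExposureSummary",
    "spl",
    "spl_peak",
    "sel",
    "sel_ss",
    "sel_cum",
    "sel_cum_practical",
    "mean_inter_peak",
    "summarize_exposure",
]


def spl(x: PressureSeries) -> float:
    """Sound pressure level over the whole series, dB re 1 uPa."""
    if x.n_samples == 0:
        raise ValueError("empty pressure series")
    msq = float(np.mean(x.samples**2))
    if msq == 0.0:
        return DB_SENTINEL
    return 10.0 * math.log10(msq / P_REF_PA**2)


def spl_peak(x: PressureSeries) -> float:
    """Peak level: 20*log10 of the maximum absolute pressure, dB re 1 uPa."""
    if x.n_samples == 0:
        raise ValueError("empty pressure series")
    peak = float(np.max(np.abs(x.samples)))
    if peak == 0.0:
        return DB_SENTINEL
    return 20.0 * math.log10(peak / P_REF_PA)


def sel(x: PressureSeries) -> float:
    """Sound exposure level: time integral of p^2, dB re 1 uPa^2 s."""
    if x.n_samples == 0:
        raise ValueError("empty pressure series")
    energy = float(np.sum(x.samples**2)) / x.sample_rate
    if energy == 0.0:
        return DB_SENTINEL
    return 10.0 * math.log10(energy / P_REF_PA**2)


def sel_ss(x: PressureSeries, e: StrikeEvent) -> float:
    """Single-strike SEL: the SEL of the event's window within ``x``."""
    return sel(extract_event_segment(x, e))


def sel_cum(sel_ss_values: Sequence[float]) -> float:
    """Cumulative SEL: decibel sum 10*log10(sum 10^(SEL_i/10)).

    Sentinel (-inf) entries contribute zero energy.
    """
    vals = np.asarray(sel_ss_values, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("sel_cum requires at least one event")
    total = float(np.sum(10.0 ** (vals / 10.0)))
    if total == 0.0:
        return DB_SENTINEL
    return 10.0 * math.log10(total)


def sel_cum_practical(mean_sel_ss: float, n_events: int) -> float:
    """Practical cumulative level: mean SEL_ss + 10*log10(N)."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    return mean_sel_ss + 10.0 * math.log10(n_events)


def mean_inter_peak(events: Sequence[StrikeEvent]) -> float:
    """Arithmetic mean of successive crossing-time differences, seconds."""
    if len(events) < 2:
        raise ValueError("need at least two events for an inter-peak interval")
    t = np.array([e.t_cross for e in events])
    return float(np.mean(np.diff(t)))


@dataclass
class ExposureSummary:
    """Per-recording exposure report (one row of a sound-metrics table)."""

    n_events: int
    mean_inter_peak_s: float
    sel_ss_mean_db: float
    sel_ss_max_db: float
    sel_ss_min_db: float
    spl_peak_db: float
    sel_cum_db: float
    sel_cum_p_db: float
    spl_db: float
    dominant_band_hz: float

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.n_events > 0 and all(
            math.isfinite(v)
            for v in (self.sel_ss_min_db, self.sel_ss_mean_db, self.sel_ss_max_db)
        ):
            if not (
                self.sel_ss_min_db <= self.sel_ss_mean_db + 1e-9
                and self.sel_ss_mean_db <= self.sel_ss_max_db + 1e-9
            ):
                raise ValueError("require sel_ss min <= mean <= max")

    def as_row(self) -> dict:
        return asdict(self)

    def as_rounded_row(self) -> dict:
        """Integer-dB view matching report-table conventions."""
        row = self.as_row()
        for k, v in list(row.items()):
            if k.endswith("_db") and math.isfinite(v):
                row[k] = round_db(v)
        return row


def summarize_exposure(
    x: PressureSeries,
    events: Sequence[StrikeEvent],
    spectrum: ThirdOctaveSpectrum | None = None,
    mean_sel_mode: str = "db",
) -> ExposureSummary:
    """Assemble the per-recording exposure summary.

    ``mean_sel_mode`` selects how the "average SEL_ss" entering the
    practical cumulative level is formed: ``"db"`` (default) takes the
    arithmetic mean of the per-event dB values, matching how exposure
    tables print mean/min/max per-strike levels; ``"energy"`` takes the
    energy-domain mean (``sel_cum - 10*log10(N)``), which makes the
    practical formula exact by construction.

    With zero events the SEL fields carry the ``-inf`` sentinel while the
    broadband SPL and dominant band still describe the (ambient) recording.
    """
    if mean_sel_mode not in ("db", "energy"):
        raise ValueError("mean_sel_mode must be 'db' or 'energy'")
    n = len(events)
    nan = math.nan
    if n == 0:
        return ExposureSummary(
            n_events=0,
            mean_inter_peak_s=nan,
            sel_ss_mean_db=DB_SENTINEL,
            sel_ss_max_db=DB_SENTINEL,
            sel_ss_min_db=DB_SENTINEL,
            spl_peak_db=spl_peak(x),
            sel_cum_db=DB_SENTINEL,
            sel_cum_p_db=DB_SENTINEL,
            spl_db=spl(x),
            dominant_band_hz=dominant_band(spectrum) if spectrum else nan,
        )
    sels = np.array([sel_ss(x, e) for e in events])
    cum = sel_cum(sels)
    if mean_sel_mode == "db":
        mean_sel = float(np.mean(sels))
    else:
        mean_sel = cum - 10.0 * math.log10(n)
    return ExposureSummary(
        n_events=n,
        mean_inter_peak_s=mean_inter_peak(events) if n >= 2 else nan,
        sel_ss_mean_db=mean_sel,
        sel_ss_max_db=float(np.max(sels)),
        sel_ss_min_db=float(np.min(sels)),
        spl_peak_db=spl_peak(x),
        sel_cum_db=cum,
        sel_cum_p_db=sel_cum_practical(mean_sel, n),
        spl_db=spl(x),
        dominant_band_hz=dominant_band(spectrum) if spectrum else nan,
    )
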