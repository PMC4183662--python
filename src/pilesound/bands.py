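"""One-third-octave band analysis of pressure segments.

Bands follow the base-10 definition: exact centers ``fc = 1000 * 10^(n/10)``
Hz with edges at ``fc * 10^(+/-1/20)``, so adjacent bands tile the axis
exactly.  Centers are labelled with the nominal preferred values used in
acoustics reports (25, 31.5, 40, ..., 125, 160, 200 Hz ...).

Band energies are obtained by rectangular integration of the FFT
periodogram over each band's half-open ``[lower, upper)`` edge interval —
exactly Parseval-consistent with the broadband sound exposure, unlike a
time-domain filter bank.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import DB_SENTINEL, PressureSeries
from .detection import P_REF_PA

__all__ = [
    "Band",
    "ThirdOctaveSpectrum",
    "third_octave_bands",
    "band_levels",
    "mean_event_spectrum",
    "dominant_band",
]

#: nominal 1/3-octave center labels for one decade (ANSI/IEC preferred values)
_NOMINAL_DECADE = (1.0, 1.25, 1.6, 2.0, 2.5, 3.15, 4.0, 5.0, 6.3, 8.0)


@dataclass(frozen=True)
class Band:
    """One 1/3-octave band: nominal center label plus exact edges in Hz."""

    center: float  # nominal label, e.g. 31.5
    lower: float  # exact lower edge, fc_exact / 10^(1/20)
    upper: float  # exact upper edge, fc_exact * 10^(1/20)


@dataclass
class ThirdOctaveSpectrum:
    """Per-band levels (SEL in dB re 1 uPa^2 s, or SPL in dB re 1 uPa)."""

    bands: tuple[Band, ...]
    levels: np.ndarray
    metric_kind: str  # "SEL" | "SPL"

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)
        if self.metric_kind not in ("SEL", "SPL"):
            raise ValueError("metric_kind must be 'SEL' or 'SPL'")
        if len(self.bands) != self.levels.size:
            raise ValueError("one level per band required")
        centers = [b.center for b in self.bands]
        if any(a >= b for a, b in zip(centers, centers[1:])):
            raise ValueError("band centers must be strictly increasing")

    @property
    def band_centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])


def _nominal_label(fc_exact: float) -> float:
    """Snap an exact base-10 center to its nominal preferred label."""
    decade = 10.0 ** math.floor(math.log10(fc_exact) + 1e-9)
    ratio = fc_exact / decade
    label = min(_NOMINAL_DECADE, key=lambda v: abs(math.log10(v / ratio)))
    nominal = label * decade
    # drop float fuzz: 31.499999 -> 31.5
    return float(f"{nominal:.6g}")


def third_octave_bands(f_min: float, f_max: float) -> list[Band]:
    """Standard 1/3-octave bands whose nominal centers lie in [f_min, f_max]."""
    if not (0 < f_min < f_max):
        raise ValueError("require 0 < f_min < f_max")
    n_lo = math.floor(10 * math.log10(f_min / 1000.0)) - 1
    n_hi = math.ceil(10 * math.log10(f_max / 1000.0)) + 1
    bands = []
    for n in range(n_lo, n_hi + 1):
        fc = 1000.0 * 10.0 ** (n / 10.0)
        label = _nominal_label(fc)
        if f_min - 1e-9 <= label <= f_max + 1e-9:
            bands.append(Band(label, fc * 10.0 ** (-1 / 20), fc * 10.0 ** (1 / 20)))
    if not bands:
        raise ValueError(f"no 1/3-octave centers inside [{f_min}, {f_max}] Hz")
    return bands


def _periodogram_energy(x: PressureSeries) -> tuple[np.ndarray, np.ndarray]:
    """Frequencies and per-bin signal energy (uPa^2 s), Parseval-exact.

    Energy here is the time integral of squared pressure; summing all bins
    (DC and Nyquist included) reproduces ``sum(p^2) * dt`` exactly.
    """
    n = x.n_samples
    X = np.fft.rfft(x.samples / P_REF_PA)
    freqs = np.fft.rfftfreq(n, d=1.0 / x.sample_rate)
    w = np.full(freqs.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    energy = w * np.abs(X) ** 2 / (n * x.sample_rate)
    return freqs, energy


def band_levels(
    x: PressureSeries, bands: Sequence[Band], metric_kind: str = "SEL"
) -> ThirdOctaveSpectrum:
    """Integrate the periodogram over each band's [lower, upper) interval.

    SEL bands report 10*log10 of the band's time-integrated squared
    pressure (dB re 1 uPa^2 s); SPL bands use the time-mean-square
    convention, i.e. SEL minus 10*log10(duration).
    """
    if x.n_samples == 0:
        raise ValueError("empty segment")
    nyquist = x.sample_rate / 2.0
    kept = [b for b in bands if b.lower < nyquist]
    if len(kept) < len(bands):
        warnings.warn(
            f"dropped {len(bands) - len(kept)} band(s) above Nyquist ({nyquist} Hz)",
            stacklevel=2,
        )
    freqs, energy = _periodogram_energy(x)
    levels = np.empty(len(kept))
    for i, b in enumerate(kept):
        sel_bins = (freqs >= b.lower) & (freqs < b.upper)
        e = float(energy[sel_bins].sum())
        if e <= 0:
            levels[i] = DB_SENTINEL
        elif metric_kind == "SEL":
            levels[i] = 10.0 * math.log10(e)
        else:
            levels[i] = 10.0 * math.log10(e / x.duration)
    return ThirdOctaveSpectrum(tuple(kept), levels, metric_kind)


def mean_event_spectrum(
    spectra: Sequence[ThirdOctaveSpectrum],
) -> ThirdOctaveSpectrum:
    """Energy-domain mean across event spectra: 10*log10(mean(10^(L/10))).

    All spectra must share the same band grid and metric kind.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if s.bands != first.bands or s.metric_kind != first.metric_kind:
            raise ValueError("spectra have mixed band grids or metric kinds")
    stack = np.vstack([10.0 ** (s.levels / 10.0) for s in spectra])
    with np.errstate(divide="ignore"):
        mean_levels = 10.0 * np.log10(stack.mean(axis=0))
    return ThirdOctaveSpectrum(first.bands, mean_levels, first.metric_kind)


def dominant_band(s: ThirdOctaveSpectrum) -> float:
    """Center frequency (nominal Hz) of the band with most energy.

    Ties resolve to the lowest center.
    """
    if not s.bands:
        raise ValueError("empty spectrum")
    i = int(np.argmax(s.levels))  # argmax returns the first (lowest) maximum
    return s.bands[i].center
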