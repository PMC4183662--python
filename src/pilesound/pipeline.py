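"""End-to-end runs: analyze a recording, simulate scenes, run the stats.

Each run writes its artifacts plus a ``manifest.json`` capturing the
configuration, seed, input checksums and library versions, sufficient to
reproduce the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CalibrationChain,
    PressureSeries,
    read_recording,
    write_table,
    write_wav,
)
from .detection import DetectionConfig, compute_spl_series, detect_strikes, extract_event_segment
from .bands import band_levels, mean_event_spectrum, third_octave_bands, ThirdOctaveSpectrum
from .metrics import ExposureSummary, summarize_exposure
from .stats import (
    permanova,
    immediate_mortality_response,
    delayed_mortality_response,
)
from .synth import MortalityDesignSpec, StrikeSceneSpec, synth_mortality, synth_scene

__all__ = ["RunConfig", "analyze", "run_analyze", "run_simulate_scene",
           "run_simulate_mortality", "run_stats"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for an analysis run."""

    calibration: CalibrationChain = CalibrationChain()
    detection: DetectionConfig = DetectionConfig()
    band_f_min: float = 20.0
    band_f_max: float = 16000.0
    mean_sel_mode: str = "db"

    def to_dict(self) -> dict:
        return {
            "calibration": dataclasses.asdict(self.calibration),
            "detection": dataclasses.asdict(self.detection),
            "band_f_min": self.band_f_min,
            "band_f_max": self.band_f_max,
            "mean_sel_mode": self.mean_sel_mode,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, cfg_dict: dict, inputs: dict[str, Path], seed=None) -> None:
    manifest = {
        "pilesound_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "seed": seed,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def analyze(
    x: PressureSeries, cfg: RunConfig = RunConfig()
) -> tuple[ExposureSummary, list, ThirdOctaveSpectrum]:
    """Run the full exposure analysis on a calibrated pressure series.

    Pipeline: SPL time series -> strike detection -> per-event SEL and
    third-octave spectra -> recording summary.  With zero detected events
    (a control recording) the reported spectrum is the broadband SPL
    spectrum of the whole recording.
    """
    det = cfg.detection
    spl_series = compute_spl_series(x, det.spl_window_s, det.spl_hop_s)
    events = detect_strikes(spl_series, det, signal_t0=x.t0, signal_duration=x.duration)
    f_max = min(cfg.band_f_max, x.sample_rate / 2 / 10 ** (1 / 20))
    bands = third_octave_bands(cfg.band_f_min, f_max)
    if events:
        spectra = [
            band_levels(extract_event_segment(x, e), bands, "SEL") for e in events
        ]
        spectrum = mean_event_spectrum(spectra)
    else:
        spectrum = band_levels(x, bands, "SPL")
    summary = summarize_exposure(x, events, spectrum, mean_sel_mode=cfg.mean_sel_mode)
    return summary, events, spectrum


def run_analyze(
    wav_path: str | Path,
    outdir: str | Path,
    cfg: RunConfig = RunConfig(),
) -> ExposureSummary:
    """Analyze a WAV file and write summary, event and spectrum tables."""
    wav_path = Path(wav_path)
    x = read_recording(wav_path, cfg.calibration)
    summary, events, spectrum = analyze(x, cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table([summary.as_row()], outdir / "summary.csv")
    write_table(
        [
            {
                "index": e.index,
                "t_cross_s": e.t_cross,
                "t_start_s": e.t_start,
                "t_end_s": e.t_end,
                "truncated": e.truncated,
            }
            for e in events
        ]
        or [],
        outdir / "events.csv",
    )
    write_table(
        [
            {
                "band_center_hz": b.center,
                "level_db": float(l),
                "metric_kind": spectrum.metric_kind,
            }
            for b, l in zip(spectrum.bands, spectrum.levels)
        ],
        outdir / "spectrum.csv",
    )
    _write_manifest(outdir, cfg.to_dict(), {"wav": wav_path})
    return summary


def run_simulate_scene(
    spec: StrikeSceneSpec,
    outdir: str | Path,
    chain: CalibrationChain = CalibrationChain(),
) -> Path:
    """Render a synthetic scene to a float32 WAV plus a truth CSV.

    The WAV stores samples scaled by the inverse of ``chain`` (default: the
    standard chain), so analyzing it with the same calibration recovers the
    synthesized pressures exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series, truth = synth_scene(spec)
    wav_path = outdir / "scene.wav"
    write_wav(wav_path, series, chain)
    truth.to_frame().to_csv(outdir / "truth.csv", index=False)
    _write_manifest(outdir, dataclasses.asdict(spec), {}, seed=spec.seed)
    return wav_path


def run_simulate_mortality(spec: MortalityDesignSpec, outdir: str | Path) -> Path:
    """Simulate a mortality experiment and write the long-format table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = synth_mortality(spec)
    out = outdir / "mortality.csv"
    table.to_csv(out, index=False)
    _write_manifest(
        outdir,
        {"groups": [dataclasses.asdict(g) for g in spec.groups], "days": spec.days},
        {},
        seed=spec.seed,
    )
    return out


def run_stats(
    mortality_csv: str | Path,
    design: str,
    n_perm: int,
    seed: int,
    outdir: str | Path,
) -> dict:
    """PERMANOVA on a mortality table; writes a JSON stats report.

    ``design`` is ``"immediate"`` (two factors: treatment, age; response is
    the per-vial day-0 proportion dead) or ``"delayed"`` (three factors:
    treatment, age, day; per-vial daily cumulative proportions).
    """
    path = Path(mortality_csv)
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed mortality CSV {path}: {exc}") from exc
    if design == "immediate":
        y, factors = immediate_mortality_response(table)
        order = ["treatment", "age", "treatment:age"]
    elif design == "delayed":
        y, factors = delayed_mortality_response(table)
        order = ["treatment", "age", "day", "treatment:age"]
    else:
        raise ValueError("design must be 'immediate' or 'delayed'")
    result = permanova(y, factors, order, n_perm=n_perm, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = result.to_dict()
    report["design"] = design
    with open(outdir / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_manifest(outdir, {"design": design, "n_perm": n_perm, "order": order},
                    {"mortality": path}, seed=seed)
    return report
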