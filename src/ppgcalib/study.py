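"""One-command simulated study: sweep, calibrate, capture, analyze, report.

Reproduces the whole bench validation in software for each configured
device: a brightness sweep is captured and line-fitted to characterize the
zero light offset; the pulse protocol is rendered once and captured twice
— under the automatic (shifted-sRGB) tone map and under the linear one,
mirroring the bench practice of replaying identical commanded signals —
and three ratio-of-ratios series are compared against ground truth:
Default automatic (uncorrected), Uncalibrated linear, and Calibrated
linear (ZLO-corrected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from . import bench
from .calibration import CalibrationResult, average_calibrations, fit_zlo
from .camera import CameraModel, capture
from .config import CameraConfig, RunConfig
from .errors import ConfigurationError
from .evaluation import (
    AgreementStats,
    PairedComparison,
    agreement,
    build_report,
    compare_paired,
    report_text,
)
from .io import write_calibration, write_sweep, write_table, write_trace
from .pipeline import PixelTrace, analyze_trace, select_segments

logger = logging.getLogger("ppgcalib")

SETTING_AUTOMATIC = "Default automatic"
SETTING_UNCALIBRATED = "Uncalibrated linear"
SETTING_CALIBRATED = "Calibrated linear"

# Independent noise streams per device, derived from the device seed.
_STREAM_SWEEP, _STREAM_LINEAR, _STREAM_AUTOMATIC = 0, 1, 2


def _rng(device_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([device_seed, stream])


def capture_trace(
    camera: CameraModel,
    schedule: bench.PulseSchedule,
    rng: np.random.Generator | None = None,
) -> PixelTrace:
    """Capture a rendered pulse schedule into a pixel trace."""
    pixels = capture(camera, schedule.brightness, rng=rng)
    return PixelTrace(timestamps_ms=schedule.timestamps_ms, channels=pixels)


def calibrate_device(
    device: CameraConfig, sweep_schedule: bench.SweepSchedule
) -> tuple[dict[str, np.ndarray], CalibrationResult]:
    """Capture a sweep on a device (linear tone map) and fit its ZLO.

    The sweep drives all channels identically; the red and green fits are
    averaged into the single per-model ZLO used for both wavelengths.
    """
    camera = device.to_camera("linear")
    b = sweep_schedule.brightness
    pixels = capture(
        camera,
        {"red": b, "green": b, "blue": b},
        rng=_rng(device.seed, _STREAM_SWEEP),
    )
    fits = [
        fit_zlo(b, pixels[ch], model_name=device.name) for ch in ("red", "green")
    ]
    return pixels, average_calibrations(fits)


@dataclass
class DeviceResult:
    """Everything the study produced for one simulated device."""

    name: str
    calibration: CalibrationResult
    ror_linear: pd.DataFrame
    ror_automatic: pd.DataFrame
    selected: pd.DataFrame
    stats: Dict[str, AgreementStats]
    comparisons: Dict[str, PairedComparison]


@dataclass
class StudyResult:
    report: pd.DataFrame
    text: str
    devices: Dict[str, DeviceResult]
    ground_truth: pd.DataFrame
    config: RunConfig


def _slug(name: str) -> str:
    return name.lower().replace(" ", "_")


def run_study(config: RunConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Execute the full study described by ``config``.

    Deterministic for a fixed config (all randomness is seeded).  When
    ``out_dir`` is given, every intermediate (sweeps, traces, per-segment
    RoR tables, calibration records) and the final report are written
    there.

    Raises
    ------
    ConfigurationError
        If the analysis segment count does not match the pulse protocol's
        combination count (segments must align with combinations for
        ground-truth pairing).
    """
    if not config.devices:
        raise ConfigurationError("study requires at least one device")
    n_seg = config.analysis.n_segments
    if n_seg != config.pulse.n_combinations:
        raise ConfigurationError(
            "analysis.n_segments must equal pulse.n_combinations for ground-truth alignment"
        )

    protocol = config.pulse.to_protocol()
    schedule = bench.render_pulses(protocol)
    gt = bench.ground_truth_table(protocol)
    gt_ror = gt["ror"].to_numpy()
    sweep_schedule = bench.make_sweep(config.sweep.to_protocol())

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "config.json")
        write_table(gt, out / "ground_truth.csv")

    tables: Dict[str, Mapping] = {}
    devices: Dict[str, DeviceResult] = {}
    for i, dev in enumerate(config.devices):
        logger.info("device=%s seed=%d stage=calibrate", dev.name, dev.seed)
        sweep_pixels, calib = calibrate_device(dev, sweep_schedule)

        logger.info("device=%s stage=capture", dev.name)
        trace_lin = capture_trace(
            dev.to_camera("linear"), schedule, _rng(dev.seed, _STREAM_LINEAR)
        )
        trace_auto = capture_trace(
            dev.to_camera("automatic"), schedule, _rng(dev.seed, _STREAM_AUTOMATIC)
        )

        logger.info("device=%s stage=analyze", dev.name)
        df_lin = analyze_trace(trace_lin, n_seg, zlo=calib.zlo, ground_truth=gt_ror)
        df_auto = analyze_trace(trace_auto, n_seg, ground_truth=gt_ror)

        # Segments must be usable under every setting so the three series
        # stay paired segment-by-segment.
        common_valid = (
            df_lin["valid"]
            & df_auto["valid"]
            & df_lin["ror_calibrated"].notna()
            & df_auto["ror_uncalibrated"].notna()
        )
        sel = select_segments(
            df_lin.assign(valid=common_valid),
            config.analysis.k_selected,
            config.analysis.seed + i,
        )
        idx = sel.index
        truth = gt_ror[sel["segment"].to_numpy()]
        series = {
            SETTING_AUTOMATIC: df_auto.loc[idx, "ror_uncalibrated"].to_numpy(),
            SETTING_UNCALIBRATED: df_lin.loc[idx, "ror_uncalibrated"].to_numpy(),
            SETTING_CALIBRATED: df_lin.loc[idx, "ror_calibrated"].to_numpy(),
        }
        tables[dev.name] = {name: (vals, truth) for name, vals in series.items()}
        stats = {name: agreement(vals, truth) for name, vals in series.items()}
        comparisons = {
            "calibrated_vs_uncalibrated": compare_paired(
                np.abs(series[SETTING_UNCALIBRATED] - truth),
                np.abs(series[SETTING_CALIBRATED] - truth),
            ),
            "calibrated_vs_automatic": compare_paired(
                np.abs(series[SETTING_AUTOMATIC] - truth),
                np.abs(series[SETTING_CALIBRATED] - truth),
            ),
        }
        selected = pd.DataFrame(
            {
                "segment": sel["segment"].to_numpy(),
                "ground_truth": truth,
                "ror_automatic": series[SETTING_AUTOMATIC],
                "ror_uncalibrated": series[SETTING_UNCALIBRATED],
                "ror_calibrated": series[SETTING_CALIBRATED],
            }
        )
        devices[dev.name] = DeviceResult(
            name=dev.name,
            calibration=calib,
            ror_linear=df_lin,
            ror_automatic=df_auto,
            selected=selected,
            stats=stats,
            comparisons=comparisons,
        )

        if out is not None:
            ddir = out / _slug(dev.name)
            ddir.mkdir(exist_ok=True)
            write_sweep(sweep_schedule.brightness, sweep_pixels, ddir / "sweep.csv")
            write_calibration(calib, ddir / "calibration.json")
            write_trace(trace_lin, ddir / "trace_linear.csv")
            write_trace(trace_auto, ddir / "trace_automatic.csv")
            write_table(df_lin, ddir / "ror_linear.csv")
            write_table(df_auto, ddir / "ror_automatic.csv")
            write_table(selected, ddir / "selected.csv")

    report = build_report(tables, config.settings)
    header = f"# ppgcalib study report  config_hash={config.config_hash()}"
    text = report_text(report, header=header)
    if out is not None:
        report.to_csv(out / "report.csv")
        (out / "report.txt").write_text(text)
    return StudyResult(
        report=report, text=text, devices=devices, ground_truth=gt, config=config
    )
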