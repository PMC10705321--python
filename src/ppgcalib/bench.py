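"""Software emulation of the LED calibration test bench.

The physical bench drives an RGB LED with PWM inside a dark shield so that
the camera sees a controllable, reproducible brightness.  Two schedules
matter:

* a **calibration sweep** — brightness increased linearly from zero to
  full scale, used to fit the camera's linear response and its zero light
  offset (ZLO);
* a **pulse protocol** — square "PPG pulses" whose commanded DC (trough)
  and AC (peak minus trough) levels per channel realize a known
  ratio-of-ratios (RoR), the quantity pulse oximetry is built on:

      RoR = [AC1 / (AC1 + DC1)] / [AC2 / (AC2 + DC2)]

  with channel 1 = red and channel 2 = green.

Brightness is expressed as PWM duty fraction times ``FULL_SCALE_BRIGHTNESS``,
chosen so a unit-gain camera reads close to 250 at 100% duty — the pixel
pre-selection level that keeps the recording unsaturated while using most
of the 8-bit range.  PWM itself (32 MHz in hardware, far above any frame
rate) is abstracted to its duty-cycle mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ProtocolError

#: Brightness units at 100% PWM duty: a unit-gain, zero-offset camera
#: reads ~250 of 255 here, mirroring the bench pixel pre-selection.
FULL_SCALE_BRIGHTNESS = 250.0

#: One frame per 30 ms exposure.
DEFAULT_FRAME_RATE_HZ = 100.0 / 3.0


@dataclass(frozen=True)
class SweepProtocol:
    """Linearly increasing brightness staircase for ZLO characterization."""

    n_steps: int = 101
    frames_per_step: int = 3
    full_scale: float = FULL_SCALE_BRIGHTNESS

    def __post_init__(self) -> None:
        if self.n_steps < 3:
            raise ProtocolError("sweep needs at least 3 levels for a line fit")
        if self.frames_per_step < 1:
            raise ProtocolError("frames_per_step must be >= 1")
        if self.full_scale <= 0:
            raise ProtocolError("full_scale must be positive")


@dataclass(frozen=True)
class SweepSchedule:
    """Rendered sweep: one brightness value per frame."""

    levels: np.ndarray
    brightness: np.ndarray  # per-frame commanded brightness
    protocol: SweepProtocol


def make_sweep(protocol: SweepProtocol) -> SweepSchedule:
    """Render a sweep protocol into a stepwise per-frame schedule.

    Levels are equally spaced from 0 to full scale inclusive; each level
    is held for ``frames_per_step`` frames.
    """
    levels = np.linspace(0.0, protocol.full_scale, protocol.n_steps)
    brightness = np.repeat(levels, protocol.frames_per_step)
    return SweepSchedule(levels=levels, brightness=brightness, protocol=protocol)


@dataclass(frozen=True)
class Combination:
    """One commanded DC/AC pair per channel with its exact ground-truth RoR."""

    dc: Mapping[str, float]
    ac: Mapping[str, float]
    ror: float


def ror_from_commanded(ac1: float, dc1: float, ac2: float, dc2: float) -> float:
    """Ratio of ratios on commanded (noise-free) brightness levels."""
    return (ac1 / (ac1 + dc1)) / (ac2 / (ac2 + dc2))


@dataclass(frozen=True)
class PulseProtocol:
    """Commanded square-pulse protocol with known per-combination RoR.

    ``channels`` orders the wavelength pair as (channel 1, channel 2) =
    (red, green).  Each combination is repeated ``repetitions`` times as a
    square pulse (trough = DC, peak = DC + AC) held for ``plateau_ms``,
    with ``gap_ms`` at trough level between repetitions.
    """

    combinations: Tuple[Combination, ...]
    repetitions: int = 5
    gap_ms: float = 100.0
    plateau_ms: float = 300.0
    frame_rate: float = DEFAULT_FRAME_RATE_HZ
    full_scale: float = FULL_SCALE_BRIGHTNESS
    channels: Tuple[str, str] = ("red", "green")
    ror_range: Tuple[float, float] = (0.5, 2.0)
    rng_seed: int = 0

    @property
    def n_combinations(self) -> int:
        return len(self.combinations)


def ground_truth_table(protocol: PulseProtocol) -> pd.DataFrame:
    """Per-combination commanded AC/DC levels and exact RoR as a table."""
    ch1, ch2 = protocol.channels
    rows = []
    for i, c in enumerate(protocol.combinations):
        rows.append(
            {
                "combination": i,
                f"dc_{ch1}": c.dc[ch1],
                f"ac_{ch1}": c.ac[ch1],
                f"dc_{ch2}": c.dc[ch2],
                f"ac_{ch2}": c.ac[ch2],
                "ror": c.ror,
            }
        )
    return pd.DataFrame(rows)


def sample_ror_protocol(
    n: int = 100,
    ror_range: Tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
    *,
    dc_range: Tuple[float, float] = (0.2, 0.7),
    ac2_range: Tuple[float, float] = (0.05, 0.25),
    repetitions: int = 5,
    gap_ms: float = 100.0,
    plateau_ms: float = 300.0,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
    full_scale: float = FULL_SCALE_BRIGHTNESS,
    channels: Tuple[str, str] = ("red", "green"),
    max_retries: int = 1000,
) -> PulseProtocol:
    """Randomly sample ``n`` DC/AC combinations hitting target RoRs exactly.

    Target RoRs are drawn uniformly over ``ror_range``.  DC levels (both
    channels) are drawn uniformly from ``dc_range`` (fractions of full
    scale) and the channel-2 AC from ``ac2_range``; the channel-1 AC is
    then solved in closed form so the commanded RoR equals the target
    exactly: with q = target * AC2/(AC2 + DC2), AC1 = q * DC1 / (1 - q).
    Draws whose solved AC1 is non-positive or would exceed full-scale
    headroom (peak brightness above 100% duty) are rejected and redrawn.

    Deterministic for a fixed seed.

    Raises
    ------
    ProtocolError
        If ``n < 1``, the RoR range is not a positive interval, or a
        feasible combination cannot be found within ``max_retries`` draws.
    """
    if n < 1:
        raise ProtocolError("need at least one combination")
    lo, hi = ror_range
    if not (0.0 < lo < hi):
        raise ProtocolError("ror_range must be a positive, increasing interval")
    rng = np.random.default_rng(seed)
    ch1, ch2 = channels
    combos: list[Combination] = []
    for _ in range(n):
        for _attempt in range(max_retries):
            target = rng.uniform(lo, hi)
            dc1 = rng.uniform(*dc_range) * full_scale
            dc2 = rng.uniform(*dc_range) * full_scale
            ac2 = rng.uniform(*ac2_range) * full_scale
            q = target * ac2 / (ac2 + dc2)
            if not 0.0 < q < 1.0:
                continue
            ac1 = q * dc1 / (1.0 - q)
            if ac1 <= 0.0 or ac1 + dc1 > full_scale or ac2 + dc2 > full_scale:
                continue
            combos.append(
                Combination(
                    dc={ch1: dc1, ch2: dc2},
                    ac={ch1: ac1, ch2: ac2},
                    ror=ror_from_commanded(ac1, dc1, ac2, dc2),
                )
            )
            break
        else:
            raise ProtocolError(
                f"could not sample a feasible DC/AC combination in {max_retries} draws"
            )
    return PulseProtocol(
        combinations=tuple(combos),
        repetitions=repetitions,
        gap_ms=gap_ms,
        plateau_ms=plateau_ms,
        frame_rate=frame_rate,
        full_scale=full_scale,
        channels=channels,
        ror_range=(lo, hi),
        rng_seed=seed,
    )


@dataclass(frozen=True)
class PulseSchedule:
    """Rendered pulse protocol: per-frame commanded brightness per channel."""

    timestamps_ms: np.ndarray
    brightness: Mapping[str, np.ndarray]
    frames_per_combination: int
    protocol: PulseProtocol


def render_pulses(protocol: PulseProtocol) -> PulseSchedule:
    """Render a pulse protocol into per-frame commanded brightness.

    Each combination renders as: a leading gap at trough level, then
    ``repetitions`` x (peak plateau, gap at trough).  All combinations
    yield the same frame count, so equal-length segmentation downstream
    aligns segment boundaries with combination boundaries.  The blue
    channel is held dark (the validation uses red and green only).
    """
    frame_ms = 1000.0 / protocol.frame_rate
    n_plateau = max(1, round(protocol.plateau_ms / frame_ms))
    n_gap = max(1, round(protocol.gap_ms / frame_ms))
    frames_per_combination = n_gap + protocol.repetitions * (n_plateau + n_gap)

    peak_mask = np.zeros(frames_per_combination, dtype=bool)
    pos = n_gap
    for _ in range(protocol.repetitions):
        peak_mask[pos : pos + n_plateau] = True
        pos += n_plateau + n_gap

    per_channel: dict[str, list[np.ndarray]] = {ch: [] for ch in protocol.channels}
    for combo in protocol.combinations:
        for ch in protocol.channels:
            trough = combo.dc[ch]
            peak = combo.dc[ch] + combo.ac[ch]
            per_channel[ch].append(np.where(peak_mask, peak, trough))

    n_frames = frames_per_combination * protocol.n_combinations
    brightness = {ch: np.concatenate(parts) for ch, parts in per_channel.items()}
    brightness.setdefault("blue", np.zeros(n_frames))
    timestamps = np.arange(n_frames) * frame_ms
    return PulseSchedule(
        timestamps_ms=timestamps,
        brightness=brightness,
        frames_per_combination=frames_per_combination,
        protocol=protocol,
    )
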