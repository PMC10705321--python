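"""Trace analysis: segmentation, pulse features, and ratio-of-ratios.

The analysis mirrors the bench validation procedure: a two-channel pixel
trace is cut into equal-length segments (one per commanded DC/AC
combination, five pulse repetitions each), the first and last pulse of a
segment are discarded, AC is the remaining max minus min per channel and
DC the min.  Segments whose DC is zero in any channel are discarded, a
random subset is selected, and for each the uncalibrated and the
ZLO-calibrated ratio of ratios are computed:

    uncalibrated:  [AC1/(AC1 + DC1)]       / [AC2/(AC2 + DC2)]
    calibrated:    [AC1/(AC1 + DC1 - ZLO)] / [AC2/(AC2 + DC2 - ZLO)]

with channel 1 = red and channel 2 = green.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import PipelineError, UndefinedRatioError

DEFAULT_CHANNEL_PAIR: Tuple[str, str] = ("red", "green")


@dataclass
class PixelTrace:
    """Per-frame integer pixel values for each color channel.

    Timestamps are in milliseconds and must be strictly increasing;
    channels must share one length and hold integers in [0, 255].
    """

    timestamps_ms: np.ndarray
    channels: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        if self.timestamps_ms.ndim != 1:
            raise PipelineError("timestamps must be 1-D")
        if np.any(np.diff(self.timestamps_ms) <= 0):
            raise PipelineError("timestamps must be strictly increasing")
        n = len(self.timestamps_ms)
        clean: Dict[str, np.ndarray] = {}
        for ch, values in self.channels.items():
            v = np.asarray(values)
            if v.shape != (n,):
                raise PipelineError(f"channel {ch!r} length differs from timestamps")
            if not np.issubdtype(v.dtype, np.integer):
                if not np.all(v == np.round(v)):
                    raise PipelineError(f"channel {ch!r} holds non-integer pixel values")
            v = v.astype(np.int64)
            if v.min(initial=0) < 0 or v.max(initial=0) > 255:
                raise PipelineError(f"channel {ch!r} pixel values outside [0, 255]")
            clean[ch] = v
        self.channels = clean

    @property
    def n_frames(self) -> int:
        return len(self.timestamps_ms)


@dataclass(frozen=True)
class Segment:
    """A contiguous, equal-length slice of a trace (one pulse combination)."""

    index: int
    channels: Mapping[str, np.ndarray]
    n_pulses_expected: int = 5


@dataclass(frozen=True)
class PulseFeatures:
    """Per-channel AC (peak - trough) and DC (trough) of one segment.

    ``valid`` is False exactly when the DC of any analysis channel is 0;
    such segments are discarded before RoR selection.
    """

    ac: Mapping[str, float]
    dc: Mapping[str, float]
    valid: bool


def segment_trace(trace: PixelTrace, n_segments: int) -> List[Segment]:
    """Divide a trace into ``n_segments`` contiguous equal-length segments.

    Any tail remainder that does not fill a segment is dropped.

    Raises
    ------
    PipelineError
        If the trace holds fewer frames than ``n_segments``.
    """
    if n_segments < 1:
        raise PipelineError("n_segments must be >= 1")
    seg_len = trace.n_frames // n_segments
    if seg_len == 0:
        raise PipelineError(
            f"trace of {trace.n_frames} frames cannot form {n_segments} segments"
        )
    segments = []
    for i in range(n_segments):
        sl = slice(i * seg_len, (i + 1) * seg_len)
        segments.append(
            Segment(index=i, channels={ch: v[sl] for ch, v in trace.channels.items()})
        )
    return segments


def _plateau_runs(x: np.ndarray) -> List[Tuple[int, int]]:
    """Runs of frames above the segment midrange (start, end-exclusive)."""
    threshold = 0.5 * (x.max() + x.min())
    above = x > threshold
    padded = np.concatenate(([False], above, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def extract_features(
    segment: Segment,
    channels: Sequence[str] = DEFAULT_CHANNEL_PAIR,
) -> PulseFeatures:
    """Locate pulses in a segment and reduce to AC/DC per channel.

    Pulse plateaus are frames above the segment midrange (mean of max and
    min).  The first and last plateau — and everything before/after them —
    are discarded; the peak is the maximum and the trough the minimum of
    the remaining frames, so AC = peak - trough and DC = trough.  A flat
    segment yields AC = 0 with DC at its constant level.

    Raises
    ------
    PipelineError
        If a non-flat channel shows fewer than 3 pulse plateaus (nothing
        remains after discarding the first and last).
    """
    ac: Dict[str, float] = {}
    dc: Dict[str, float] = {}
    for ch in channels:
        if ch not in segment.channels:
            raise PipelineError(f"segment has no channel {ch!r}")
        x = segment.channels[ch]
        if x.max() == x.min():
            ac[ch] = 0.0
            dc[ch] = float(x[0])
            continue
        runs = _plateau_runs(x)
        if len(runs) < 3:
            raise PipelineError(
                f"channel {ch!r}: {len(runs)} pulses detected, need >= 3 to discard first/last"
            )
        inner = x[runs[0][1] : runs[-1][0]]
        ac[ch] = float(inner.max() - inner.min())
        dc[ch] = float(inner.min())
    valid = all(dc[ch] > 0 for ch in channels)
    return PulseFeatures(ac=ac, dc=dc, valid=valid)


def ror_uncalibrated(
    features: PulseFeatures,
    channel_pair: Tuple[str, str] = DEFAULT_CHANNEL_PAIR,
) -> float:
    """Uncalibrated ratio of ratios on raw pixel amplitudes."""
    ch1, ch2 = channel_pair
    ac1, dc1 = features.ac[ch1], features.dc[ch1]
    ac2, dc2 = features.ac[ch2], features.dc[ch2]
    if ac2 == 0 or (ac2 + dc2) == 0 or (ac1 + dc1) == 0:
        raise UndefinedRatioError("uncalibrated RoR undefined: zero AC or AC+DC")
    return (ac1 / (ac1 + dc1)) / (ac2 / (ac2 + dc2))


def ror_calibrated(
    features: PulseFeatures,
    zlo: float,
    channel_pair: Tuple[str, str] = DEFAULT_CHANNEL_PAIR,
) -> float:
    """ZLO-calibrated ratio of ratios: denominators are AC + DC - ZLO."""
    ch1, ch2 = channel_pair
    ac1, dc1 = features.ac[ch1], features.dc[ch1]
    ac2, dc2 = features.ac[ch2], features.dc[ch2]
    den1 = ac1 + dc1 - zlo
    den2 = ac2 + dc2 - zlo
    if den1 <= 0 or den2 <= 0:
        raise UndefinedRatioError("calibrated RoR undefined: non-positive corrected denominator")
    if ac2 == 0:
        raise UndefinedRatioError("calibrated RoR undefined: zero AC in reference channel")
    return (ac1 / den1) / (ac2 / den2)


def analyze_trace(
    trace: PixelTrace,
    n_segments: int,
    *,
    zlo: float | None = None,
    ground_truth: Sequence[float] | None = None,
    channel_pair: Tuple[str, str] = DEFAULT_CHANNEL_PAIR,
) -> pd.DataFrame:
    """Run segmentation + feature extraction + RoR over a whole trace.

    Returns one row per segment with per-channel AC/DC, a validity flag,
    the uncalibrated RoR, the calibrated RoR (NaN unless ``zlo`` given),
    and the aligned ground-truth RoR (NaN unless provided).  Segments
    whose features cannot be extracted, or whose RoR is undefined, are
    marked invalid rather than aborting the whole trace.
    """
    ch1, ch2 = channel_pair
    if ground_truth is not None and len(ground_truth) != n_segments:
        raise PipelineError("ground truth length must equal n_segments")
    rows = []
    for seg in segment_trace(trace, n_segments):
        row: Dict[str, float] = {"segment": seg.index}
        try:
            feats = extract_features(seg, channel_pair)
            row.update(
                {
                    f"ac_{ch1}": feats.ac[ch1],
                    f"dc_{ch1}": feats.dc[ch1],
                    f"ac_{ch2}": feats.ac[ch2],
                    f"dc_{ch2}": feats.dc[ch2],
                }
            )
            row["valid"] = feats.valid
            if feats.valid:
                row["ror_uncalibrated"] = ror_uncalibrated(feats, channel_pair)
                if zlo is not None:
                    row["ror_calibrated"] = ror_calibrated(feats, zlo, channel_pair)
        except PipelineError:
            row["valid"] = False
        row.setdefault("ror_uncalibrated", np.nan)
        row.setdefault("ror_calibrated", np.nan)
        row["ground_truth"] = (
            float(ground_truth[seg.index]) if ground_truth is not None else np.nan
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df["valid"] = df["valid"].astype(bool)
    return df


def select_segments(records: pd.DataFrame, k: int, seed: int) -> pd.DataFrame:
    """Uniformly select ``k`` valid segment records without replacement.

    Selection is reproducible for a fixed seed; the result is returned in
    segment order.

    Raises
    ------
    PipelineError
        If fewer than ``k`` valid records are available.
    """
    valid = records[records["valid"] & records["ror_uncalibrated"].notna()]
    if k > len(valid):
        raise PipelineError(f"requested {k} segments but only {len(valid)} are valid")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(valid.index.to_numpy(), size=k, replace=False)
    return records.loc[np.sort(chosen)]
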