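"""Forward model of a smartphone camera pipeline for contact-PPG work.

A finger-over-camera PPG measurement treats one pixel of the camera as a
photodetector.  Real smartphone pipelines are not plain photodetectors: the
image signal processor applies a *tone map* (a display-referred nonlinearity
such as the sRGB transfer curve) and the sensor itself has an intrinsic
detection threshold, visible as a non-zero y-intercept when pixel value is
regressed on incident brightness — the *zero light offset* (ZLO).

The model here is deliberately minimal:

    raw   = gain * brightness + zlo + noise        (per channel)
    raw   = max(raw, 0)                            (sub-threshold reads 0)
    pixel = clip(round(tone(raw / m) * m), 0, m)   (m = 2**bit_depth - 1)

With a linear tone curve, zero offset and no noise this is an identity up
to quantization; with a negative ``zlo`` it reproduces the floored-then-
linear response whose fitted intercept the calibration stage recovers.
Rounding is round-half-to-even.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np

from .errors import ConfigurationError, DomainError

CHANNELS = ("red", "green", "blue")

#: sRGB opto-electronic transfer constants.  The breakpoint is the exact
#: intersection of the two branches (the commonly quoted 0.0031308 is a
#: rounding that leaves a ~3e-8 jump); this keeps the curve continuous to
#: machine precision and its closed-form inverse exact.
_SRGB_A = 0.055
_SRGB_GAMMA = 2.4
_SRGB_LINEAR_SLOPE = 12.92
_SRGB_BREAK_LINEAR = 0.0031306684425006340
_SRGB_BREAK_ENCODED = _SRGB_LINEAR_SLOPE * _SRGB_BREAK_LINEAR

ArrayLike = Union[float, int, np.ndarray]


def _maybe_scalar(out: np.ndarray, inp: ArrayLike) -> ArrayLike:
    if np.ndim(inp) == 0:
        return float(out)
    return out


def srgb_transfer(linear_value: ArrayLike) -> ArrayLike:
    """sRGB opto-electronic transfer function (linear light -> encoded).

    Piecewise per IEC 61966-2-1: ``12.92 * L`` for ``L <= 0.0031308``,
    otherwise ``1.055 * L**(1/2.4) - 0.055``.  Maps [0, 1] onto [0, 1],
    is monotone increasing and continuous at the breakpoint.

    Raises
    ------
    DomainError
        If any input lies outside [0, 1].
    """
    x = np.asarray(linear_value, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0) or np.any(np.isnan(x)):
        raise DomainError("srgb_transfer input must lie in [0, 1]")
    lo = _SRGB_LINEAR_SLOPE * x
    hi = (1.0 + _SRGB_A) * np.power(np.maximum(x, _SRGB_BREAK_LINEAR), 1.0 / _SRGB_GAMMA) - _SRGB_A
    return _maybe_scalar(np.where(x <= _SRGB_BREAK_LINEAR, lo, hi), linear_value)


def srgb_inverse(encoded_value: ArrayLike) -> ArrayLike:
    """Closed-form inverse of :func:`srgb_transfer` (encoded -> linear light)."""
    y = np.asarray(encoded_value, dtype=float)
    if np.any(y < 0.0) or np.any(y > 1.0) or np.any(np.isnan(y)):
        raise DomainError("srgb_inverse input must lie in [0, 1]")
    lo = y / _SRGB_LINEAR_SLOPE
    hi = np.power((y + _SRGB_A) / (1.0 + _SRGB_A), _SRGB_GAMMA)
    return _maybe_scalar(np.where(y <= _SRGB_BREAK_ENCODED, lo, hi), encoded_value)


class ToneCurveKind(str, enum.Enum):
    """Tone-mapping behaviors a capture pipeline may apply.

    LINEAR is the identity (the CONTRAST_CURVE setting with control points
    (0, 0) and (1, 1)); SRGB is the standard display nonlinearity;
    AUTOMATIC_SHIFTED_SRGB models the adaptive default ("FAST") mode as a
    horizontally shifted sRGB curve — the best available surrogate, since
    the real algorithm is a black box.
    """

    LINEAR = "linear"
    SRGB = "srgb"
    AUTOMATIC_SHIFTED_SRGB = "automatic"


@dataclass(frozen=True)
class ToneCurve:
    """A normalized tone map from linear intensity in [0, 1] to [0, 1].

    ``shift`` is only meaningful for AUTOMATIC_SHIFTED_SRGB, where the
    curve is ``srgb(clip((x - shift) / (1 - shift), 0, 1))`` — a scene-
    dependent parameter in [0, 0.5].
    """

    kind: ToneCurveKind = ToneCurveKind.LINEAR
    shift: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.kind, ToneCurveKind):
            raise ConfigurationError(f"unknown tone curve kind: {self.kind!r}")
        if not 0.0 <= self.shift <= 0.5:
            raise ConfigurationError("tone-curve shift must lie in [0, 0.5]")

    def __call__(self, normalized_pixel: ArrayLike) -> ArrayLike:
        return apply_tone_curve(self, normalized_pixel)


def apply_tone_curve(curve: ToneCurve, normalized_pixel: ArrayLike) -> ArrayLike:
    """Apply a tone curve to a normalized intensity in [0, 1]."""
    x = np.asarray(normalized_pixel, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0) or np.any(np.isnan(x)):
        raise DomainError("tone-curve input must lie in [0, 1]")
    if curve.kind is ToneCurveKind.LINEAR:
        out = x
    elif curve.kind is ToneCurveKind.SRGB:
        out = np.asarray(srgb_transfer(x))
    elif curve.kind is ToneCurveKind.AUTOMATIC_SHIFTED_SRGB:
        rescaled = np.clip((x - curve.shift) / (1.0 - curve.shift), 0.0, 1.0)
        out = np.asarray(srgb_transfer(rescaled))
    else:  # pragma: no cover - enum is closed
        raise ConfigurationError(f"unknown tone curve kind: {curve.kind!r}")
    return _maybe_scalar(np.asarray(out), normalized_pixel)


def _default_gains() -> Mapping[str, float]:
    return {"red": 1.0, "green": 1.0, "blue": 1.0}


@dataclass(frozen=True)
class CameraModel:
    """Sensor + tone map + quantization model of one phone camera.

    Parameters
    ----------
    gains
        Pixel units per brightness unit, per color channel.  Mirrors fixed
        per-channel color-correction gains; the absolute value cancels in
        ratio-of-ratios computations.
    zlo
        Zero light offset in pixel units: the intercept of the supra-
        threshold linear response.  Typically negative (a detection
        threshold); readings that would fall below zero are floored.
    tone_curve
        Normalized tone map applied after sensor readout.
    bit_depth
        Output bit depth; pixel values are integers in [0, 2**bit_depth - 1].
    read_noise_sd
        Standard deviation of additive Gaussian read noise, pixel units.
    rng_seed
        Seed for the default noise stream when no generator is supplied.
    """

    gains: Mapping[str, float] = field(default_factory=_default_gains)
    zlo: float = 0.0
    tone_curve: ToneCurve = field(default_factory=ToneCurve)
    bit_depth: int = 8
    read_noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= int(self.bit_depth) <= 16:
            raise ConfigurationError("bit_depth must be between 1 and 16")
        if self.read_noise_sd < 0:
            raise ConfigurationError("read_noise_sd must be non-negative")
        for ch, g in self.gains.items():
            if g <= 0:
                raise ConfigurationError(f"gain for channel {ch!r} must be positive")

    @property
    def max_pixel(self) -> int:
        return 2 ** self.bit_depth - 1


def capture(
    camera: CameraModel,
    brightness: Mapping[str, ArrayLike],
    *,
    rng: np.random.Generator | None = None,
) -> dict[str, ArrayLike]:
    """Convert commanded brightness into recorded integer pixel values.

    ``brightness`` maps channel name to a scalar or 1-D array of brightness
    units (PWM duty fraction times the bench full-scale constant).  Returns
    the same structure with integer pixel values in [0, max_pixel].
    Deterministic when ``read_noise_sd == 0``; otherwise noise is drawn
    from ``rng`` (or a fresh generator seeded with ``camera.rng_seed``).

    Raises
    ------
    DomainError
        If any commanded brightness is negative.
    ConfigurationError
        If a channel has no configured gain.
    """
    if rng is None:
        rng = np.random.default_rng(camera.rng_seed)
    m = camera.max_pixel
    out: dict[str, ArrayLike] = {}
    for ch, values in brightness.items():
        if ch not in camera.gains:
            raise ConfigurationError(f"no gain configured for channel {ch!r}")
        b = np.asarray(values, dtype=float)
        if np.any(b < 0):
            raise DomainError(f"negative brightness commanded on channel {ch!r}")
        raw = camera.gains[ch] * b + camera.zlo
        if camera.read_noise_sd > 0:
            raw = raw + rng.normal(0.0, camera.read_noise_sd, size=b.shape)
        raw = np.maximum(raw, 0.0)  # sub-threshold reads as zero
        normalized = np.minimum(raw / m, 1.0)
        mapped = np.asarray(apply_tone_curve(camera.tone_curve, normalized))
        pixel = np.clip(np.round(mapped * m), 0, m).astype(np.int64)
        out[ch] = int(pixel) if np.ndim(values) == 0 else pixel
    return out
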