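"""Zero-light-offset (ZLO) characterization by sweep line fitting.

A camera pixel recorded under a linear tone map responds linearly to
incident brightness *above* its detection threshold; the fitted line's
y-intercept — the ZLO, typically negative — is the per-phone-model
constant that must be subtracted from the recorded baseline before
computing a calibrated ratio of ratios.

The fit is ordinary least squares of pixel value on commanded brightness,
after excluding floored readings (pixel at 0, where the threshold clips
the response) and near-saturated readings (pixel >= 250), both of which
would bias the intercept.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError

#: Readings at or above this pixel value are treated as near-saturated
#: and excluded from the line fit.
DEFAULT_SATURATION_EXCLUDE = 250.0


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted linear response of one phone model.

    ``slope`` is in pixel units per brightness unit and cancels in RoR
    computations; ``zlo`` (the intercept, pixel units) does not and is
    the calibration constant of interest.
    """

    slope: float
    zlo: float
    r_squared_fit: float
    n_points_used: int
    excluded_low: int
    excluded_high: int
    model_name: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(**d)


def fit_zlo(
    sweep_brightness: Sequence[float],
    sweep_pixels: Sequence[float],
    *,
    floor: float = 0.0,
    saturation: float = DEFAULT_SATURATION_EXCLUDE,
    model_name: str | None = None,
) -> CalibrationResult:
    """Fit a line to a brightness-sweep recording and return its intercept.

    Points with pixel value <= ``floor`` (threshold-clipped) or >=
    ``saturation`` are excluded; ordinary least squares is run on the
    remaining, strictly linear window.

    Raises
    ------
    CalibrationError
        If the sequences differ in length, fewer than 3 usable points
        remain, or the usable brightness values have zero variance.
    """
    b = np.asarray(sweep_brightness, dtype=float)
    p = np.asarray(sweep_pixels, dtype=float)
    if b.shape != p.shape or b.ndim != 1:
        raise CalibrationError("brightness and pixel sequences must be equal-length 1-D")
    low = p <= floor
    high = p >= saturation
    keep = ~(low | high)
    n_used = int(keep.sum())
    if n_used < 3:
        raise CalibrationError(
            f"only {n_used} usable points after excluding floored/saturated readings"
        )
    if np.ptp(b[keep]) == 0.0:
        raise CalibrationError("zero brightness variance in usable points")
    fit = stats.linregress(b[keep], p[keep])
    return CalibrationResult(
        slope=float(fit.slope),
        zlo=float(fit.intercept),
        r_squared_fit=float(fit.rvalue**2),
        n_points_used=n_used,
        excluded_low=int(low.sum()),
        excluded_high=int(high.sum()),
        model_name=model_name,
    )


def average_calibrations(results: Sequence[CalibrationResult]) -> CalibrationResult:
    """Aggregate repeated sweeps (or channels) as the mean of per-fit lines."""
    if not results:
        raise CalibrationError("no calibration results to aggregate")
    names = {r.model_name for r in results}
    return CalibrationResult(
        slope=float(np.mean([r.slope for r in results])),
        zlo=float(np.mean([r.zlo for r in results])),
        r_squared_fit=float(np.mean([r.r_squared_fit for r in results])),
        n_points_used=int(sum(r.n_points_used for r in results)),
        excluded_low=int(sum(r.excluded_low for r in results)),
        excluded_high=int(sum(r.excluded_high for r in results)),
        model_name=names.pop() if len(names) == 1 else None,
    )


def apply_zlo(dc_pixel, zlo: float):
    """ZLO-correct a recorded baseline: returns ``dc_pixel - zlo``.

    With a negative ZLO the corrected baseline is *larger* than the
    recorded one — the camera under-reports DC by the threshold amount.
    This is the denominator correction of the calibrated RoR.
    """
    return dc_pixel - zlo


def known_zlo_table() -> dict[str, float]:
    """Bundled lookup table of characterized ZLO values per phone model.

    Serves as the shared, reusable calibration record: one entry per phone
    model, applicable to other devices of the same model.
    """
    path = resources.files("ppgcalib").joinpath("data/zlo_table.json")
    return json.loads(path.read_text())
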