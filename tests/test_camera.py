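"""Camera forward-model tests: sRGB transfer, tone curves, capture."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppgcalib import (
    CameraModel,
    ToneCurve,
    ToneCurveKind,
    apply_tone_curve,
    capture,
    srgb_inverse,
    srgb_transfer,
)
from ppgcalib.errors import ConfigurationError, DomainError


class TestSrgbTransfer:
    def test_endpoints(self):
        assert srgb_transfer(0.0) == 0.0
        assert srgb_transfer(1.0) == pytest.approx(1.0, abs=1e-12)

    def test_low_light_linear_region(self):
        # 12.92 * 0.0031308; the point sits a hair above the exact branch
        # intersection, where the two branches agree to ~3e-8
        assert srgb_transfer(0.0031308) == pytest.approx(0.040449936, abs=1e-7)
        assert srgb_transfer(0.001) == pytest.approx(0.01292, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            srgb_transfer(-0.01)
        with pytest.raises(DomainError):
            srgb_transfer(1.01)

    def test_breakpoint_continuity(self):
        b = 0.0031306684425006340
        eps = 1e-12
        assert abs(srgb_transfer(b + eps) - srgb_transfer(b - eps)) < 1e-9

    def test_round_trip_through_inverse(self):
        x = np.linspace(0.0, 1.0, 1001)
        assert np.max(np.abs(srgb_inverse(srgb_transfer(x)) - x)) < 1e-9

    def test_concave_on_power_branch(self):
        x = np.linspace(0.01, 1.0, 500)
        y = np.asarray(srgb_transfer(x))
        second_diff = np.diff(y, 2)
        assert np.all(second_diff <= 1e-12)

    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    def test_monotone(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert srgb_transfer(lo) <= srgb_transfer(hi) + 1e-15


class TestToneCurve:
    def test_linear_is_identity(self):
        curve = ToneCurve(ToneCurveKind.LINEAR)
        assert apply_tone_curve(curve, 0.42) == 0.42

    def test_srgb_endpoint(self):
        assert apply_tone_curve(ToneCurve(ToneCurveKind.SRGB), 1.0) == pytest.approx(1.0)

    def test_zero_shift_automatic_reduces_to_srgb(self):
        curve = ToneCurve(ToneCurveKind.AUTOMATIC_SHIFTED_SRGB, shift=0.0)
        x = np.linspace(0, 1, 101)
        np.testing.assert_allclose(
            apply_tone_curve(curve, x), srgb_transfer(x), atol=1e-15
        )

    def test_automatic_floors_below_shift(self):
        curve = ToneCurve(ToneCurveKind.AUTOMATIC_SHIFTED_SRGB, shift=0.2)
        assert apply_tone_curve(curve, 0.1) == 0.0
        assert apply_tone_curve(curve, 1.0) == pytest.approx(1.0)

    def test_bad_shift_rejected(self):
        with pytest.raises(ConfigurationError):
            ToneCurve(ToneCurveKind.AUTOMATIC_SHIFTED_SRGB, shift=0.6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            ToneCurve("gamma22")


class TestCapture:
    def test_supra_threshold_linear(self):
        cam = CameraModel(zlo=-22.5)
        assert capture(cam, {"green": 100.0})["green"] == 78  # round(100 - 22.5)

    def test_sub_threshold_floors_at_zero(self):
        cam = CameraModel(zlo=-22.5)
        assert capture(cam, {"green": 10.0})["green"] == 0

    def test_saturation_clip(self):
        cam = CameraModel()
        assert capture(cam, {"green": 300.0})["green"] == 255

    def test_negative_brightness_rejected(self):
        with pytest.raises(DomainError):
            capture(CameraModel(), {"green": -1.0})

    def test_unknown_channel_rejected(self):
        with pytest.raises(ConfigurationError):
            capture(CameraModel(), {"uv": 1.0})

    def test_identity_reduction(self):
        # zlo = 0, linear curve, noiseless: capture is the identity up to rounding
        cam = CameraModel()
        b = np.linspace(0.0, 255.0, 511)
        px = capture(cam, {"red": b})["red"]
        np.testing.assert_array_equal(px, np.round(b).astype(int))

    def test_linearity_window_ols(self):
        # within 0 < raw < 255, a least-squares line recovers gain and zlo
        gain, zlo = 1.7, -19.6
        cam = CameraModel(gains={"red": gain, "green": 1.0, "blue": 1.0}, zlo=zlo)
        b = np.linspace(0.0, 150.0, 301)
        px = capture(cam, {"red": b})["red"]
        keep = (px > 0) & (px < 255)
        coeffs = np.polyfit(b[keep], px[keep], 1)
        assert coeffs[0] == pytest.approx(gain, abs=0.01)
        assert coeffs[1] == pytest.approx(zlo, abs=0.5)
        # every retained reading sits within rounding of the true line
        resid_true = px[keep] - (gain * b[keep] + zlo)
        assert np.max(np.abs(resid_true)) <= 0.5 + 1e-9

    @pytest.mark.parametrize(
        "curve",
        [
            ToneCurve(ToneCurveKind.LINEAR),
            ToneCurve(ToneCurveKind.SRGB),
            ToneCurve(ToneCurveKind.AUTOMATIC_SHIFTED_SRGB, shift=0.15),
        ],
    )
    def test_monotone_in_brightness(self, curve):
        cam = CameraModel(zlo=-14.9, tone_curve=curve)
        b = np.linspace(0.0, 300.0, 601)
        px = capture(cam, {"green": b})["green"]
        assert np.all(np.diff(px) >= 0)

    def test_noise_reproducible_from_seed(self):
        cam = CameraModel(zlo=-14.0, read_noise_sd=2.0, rng_seed=11)
        b = np.linspace(0, 250, 100)
        first = capture(cam, {"green": b})["green"]
        second = capture(cam, {"green": b})["green"]
        np.testing.assert_array_equal(first, second)
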