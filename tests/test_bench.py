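"""Bench-emulation tests: sweep schedules and pulse protocols."""

import numpy as np
import pytest

from ppgcalib import (
    PulseProtocol,
    SweepProtocol,
    ground_truth_table,
    make_sweep,
    render_pulses,
    ror_from_commanded,
    sample_ror_protocol,
)
from ppgcalib.bench import FULL_SCALE_BRIGHTNESS, Combination
from ppgcalib.errors import ProtocolError


class TestSweep:
    def test_linear_spacing(self):
        sched = make_sweep(SweepProtocol(n_steps=5, frames_per_step=1, full_scale=1.0))
        np.testing.assert_allclose(sched.levels, [0.0, 0.25, 0.5, 0.75, 1.0])

    def test_too_few_steps_rejected(self):
        with pytest.raises(ProtocolError):
            SweepProtocol(n_steps=2)

    def test_frame_count(self):
        sched = make_sweep(SweepProtocol(n_steps=101, frames_per_step=3))
        assert len(sched.brightness) == 303

    def test_covers_zero_to_full_scale(self):
        sched = make_sweep(SweepProtocol())
        assert sched.brightness[0] == 0.0
        assert sched.brightness[-1] == FULL_SCALE_BRIGHTNESS


class TestSampleRorProtocol:
    def test_targets_within_range(self):
        protocol = sample_ror_protocol(100, ror_range=(0.5, 2.0), seed=3)
        rors = ground_truth_table(protocol)["ror"].to_numpy()
        assert len(rors) == 100
        assert np.all((rors >= 0.5) & (rors <= 2.0))

    def test_deterministic_for_fixed_seed(self):
        a = ground_truth_table(sample_ror_protocol(50, seed=9))
        b = ground_truth_table(sample_ror_protocol(50, seed=9))
        assert a.equals(b)

    def test_different_seed_differs(self):
        a = ground_truth_table(sample_ror_protocol(50, seed=9))
        b = ground_truth_table(sample_ror_protocol(50, seed=10))
        assert not a.equals(b)

    def test_unit_target_with_equal_dcs_gives_equal_acs(self):
        # closed-form solve: target 1 with equal DCs forces AC1 = AC2
        dc, ac2, target = 120.0, 30.0, 1.0
        q = target * ac2 / (ac2 + dc)
        ac1 = q * dc / (1.0 - q)
        assert ac1 == pytest.approx(ac2, rel=1e-12)
        assert ror_from_commanded(ac1, dc, ac2, dc) == pytest.approx(1.0, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ProtocolError):
            sample_ror_protocol(0)
        with pytest.raises(ProtocolError):
            sample_ror_protocol(10, ror_range=(2.0, 0.5))
        with pytest.raises(ProtocolError):
            sample_ror_protocol(10, ror_range=(0.0, 1.0))


def _count_plateaus(x: np.ndarray) -> int:
    threshold = 0.5 * (x.max() + x.min())
    above = np.concatenate(([False], x > threshold, [False])).astype(np.int8)
    return int((np.diff(above) == 1).sum())


class TestRenderPulses:
    def test_five_plateaus_per_combination(self):
        combo = Combination(
            dc={"red": 100.0, "green": 120.0},
            ac={"red": 40.0, "green": 30.0},
            ror=ror_from_commanded(40.0, 100.0, 30.0, 120.0),
        )
        sched = render_pulses(PulseProtocol(combinations=(combo,), repetitions=5))
        assert _count_plateaus(sched.brightness["red"]) == 5

    def test_zero_ac_renders_constant(self):
        combo = Combination(dc={"red": 80.0, "green": 80.0}, ac={"red": 0.0, "green": 0.0}, ror=1.0)
        sched = render_pulses(PulseProtocol(combinations=(combo,)))
        assert np.ptp(sched.brightness["red"]) == 0.0

    def test_total_pulse_count(self):
        protocol = sample_ror_protocol(100, seed=2)
        sched = render_pulses(protocol)
        total = sum(
            _count_plateaus(part)
            for part in np.split(sched.brightness["red"], 100)
        )
        assert total == 500

    def test_ground_truth_consistent_with_rendered_levels(self):
        # Eq on the rendered plateau/trough levels recovers the target RoR
        protocol = sample_ror_protocol(20, seed=5)
        sched = render_pulses(protocol)
        fpc = sched.frames_per_combination
        for i, combo in enumerate(protocol.combinations):
            red = sched.brightness["red"][i * fpc : (i + 1) * fpc]
            green = sched.brightness["green"][i * fpc : (i + 1) * fpc]
            ror = ror_from_commanded(
                red.max() - red.min(), red.min(), green.max() - green.min(), green.min()
            )
            assert ror == pytest.approx(combo.ror, abs=1e-12)

    def test_headroom_never_exceeded(self):
        protocol = sample_ror_protocol(100, seed=8)
        sched = render_pulses(protocol)
        for ch in ("red", "green"):
            assert sched.brightness[ch].max() <= FULL_SCALE_BRIGHTNESS

    def test_equal_frames_per_combination_and_timestamps(self):
        protocol = sample_ror_protocol(10, seed=1)
        sched = render_pulses(protocol)
        assert len(sched.timestamps_ms) == 10 * sched.frames_per_combination
        dt = np.diff(sched.timestamps_ms)
        np.testing.assert_allclose(dt, dt[0])
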