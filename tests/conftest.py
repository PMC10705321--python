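import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import ppgcalib as pc
from ppgcalib.study import capture_trace


@pytest.fixture(scope="session")
def noiseless_e2e():
    """Noiseless linear-tone-map end-to-end run with a known sensor offset.

    Default pulse protocol (100 combinations, 5 reps, 0.5-2 RoR range)
    captured by a unit-gain camera with zlo = -22.5 and no read noise,
    analyzed with the same offset.
    """
    zlo = -22.5
    protocol = pc.sample_ror_protocol(100, seed=7)
    gt = pc.ground_truth_table(protocol)
    schedule = pc.render_pulses(protocol)
    camera = pc.CameraModel(zlo=zlo)
    trace = capture_trace(camera, schedule)
    records = pc.analyze_trace(trace, 100, zlo=zlo, ground_truth=gt["ror"].to_numpy())
    return {
        "zlo": zlo,
        "protocol": protocol,
        "gt": gt,
        "trace": trace,
        "records": records,
    }


@pytest.fixture(scope="session")
def study_result():
    """Full four-device simulated study with bundled ZLOs and unit read noise."""
    return pc.run_study(pc.default_study_config(seed=0))


@pytest.fixture()
def small_config():
    """Down-scaled two-device study config for fast CLI / IO tests."""
    cfg = pc.default_study_config(seed=0)
    cfg.devices = cfg.devices[:2]
    cfg.pulse.n_combinations = 20
    cfg.analysis.n_segments = 20
    cfg.analysis.k_selected = 10
    return cfg
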