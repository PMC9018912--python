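import pytest

from betadose import GroundTruth, make_protocol, simulate_accelerometer, simulate_lfp

# short schedule used throughout the unit tests: 3 steps + OFF-post,
# 14 s rest and two 2 s tapping blocks per step
SHORT_PROTOCOL_KW = dict(rest_duration_s=14.0, tap_block_duration_s=2.0,
                         inter_block_rest_s=2.0, ramp_down_s=5.0)


@pytest.fixture(scope="session")
def short_protocol():
    return make_protocol(1.5, 0.5, n_tap_blocks=2, **SHORT_PROTOCOL_KW)


@pytest.fixture(scope="session")
def default_truth():
    return GroundTruth()


@pytest.fixture(scope="session")
def short_session(short_protocol, default_truth):
    return simulate_lfp(short_protocol, default_truth, seed=42)


@pytest.fixture(scope="session")
def short_accel(short_protocol, default_truth):
    return simulate_accelerometer(short_protocol, default_truth, seed=43)
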