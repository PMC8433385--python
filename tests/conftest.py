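import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: the six-step trapping pressure ramp (MPa)
RAMP = np.array([0.000, 0.234, 0.431, 0.627, 0.824, 1.000])

#: published group-mean normalized area ramps and the slopes they reproduce
PUBLISHED_SERIES = {
    "MDA-MB-231": [1.000, 1.025, 1.085, 1.130, 1.173, 1.194],
    "MCF-7": [1.000, 1.015, 1.041, 1.061, 1.084, 1.090],
    "SKBR-3": [1.000, 1.015, 1.033, 1.055, 1.071, 1.088],
    "AHS_0.1": [1.000, 1.211, 1.312],
    "AHS_0.3": [1.000, 1.061, 1.102, 1.123, 1.154, 1.173],
    "AHS_0.6": [1.000, 1.048, 1.067, 1.068, 1.077, 1.084],
}
PUBLISHED_SLOPES = {
    "MDA-MB-231": 0.209,
    "MCF-7": 0.099,
    "SKBR-3": 0.090,
    "AHS_0.1": 0.728,
    "AHS_0.3": 0.168,
    "AHS_0.6": 0.075,
    "AHS_0.9": 0.043,
    "AHS_1.2": 0.016,
}
PUBLISHED_AHS_MODULI = {
    "AHS_0.1": (0.214, 0.082),
    "AHS_0.3": (1.603, 0.242),
    "AHS_0.6": (2.995, 0.573),
    "AHS_0.9": (6.401, 1.089),
    "AHS_1.2": (9.235, 1.634),
}
PUBLISHED_CELL_MODULI = {"MDA-MB-231": 1.527, "MCF-7": 2.650, "SKBR-3": 2.772}


@pytest.fixture(scope="session")
def published_curve():
    from acoustocalib.calibration import build_curve

    return build_curve(
        [(k, v) for k, v in PUBLISHED_SLOPES.items() if k.startswith("AHS")],
        [(k, E, sd) for k, (E, sd) in PUBLISHED_AHS_MODULI.items()],
    )


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Full synthetic study (n=20 per group) shared across tests."""
    from acoustocalib.pipeline import make_fixtures

    out = tmp_path_factory.mktemp("bundle")
    config = make_fixtures(seed=0, out_dir=out)
    return config
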