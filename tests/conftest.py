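import numpy as np
import pytest

from dcvision.core_metrics import AnalysisConfig, MotionSeries


def series(values, rate_hz=200.0, t0=0, units="px/frame", valid=None,
           source=""):
    """Shorthand MotionSeries constructor for tests."""
    return MotionSeries(np.asarray(values, dtype=float), rate_hz, t0,
                        units, valid, source)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def tracked_clip():
    """One tracked synthetic jump-then-freeze clip, shared by the video
    tests (tracking is the slow step; the clip is read-only)."""
    from dcvision.synthetic_data import Scenario, generate_test
    from dcvision.video_tracking import track

    sc = Scenario(rng_seed=42, t0_s=1.0, startle_amplitude=5.0,
                  record_s=6.0, freeze_intervals=((3.0, 5.0),),
                  baseline_motion_sd=0.3)
    test = generate_test(sc, streams=("video",))
    return test, track(test.video)
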