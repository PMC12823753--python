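import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from segrater import EvalConfig, LabelMapSequence

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def eval_config():
    return EvalConfig()


def make_sequence(frames, class_names=None, video_id="v0"):
    frames = np.asarray(frames, dtype=np.int64)
    if class_names is None:
        class_names = ["background"] + [f"s{i}" for i in range(1, int(frames.max()) + 1)]
    return LabelMapSequence(frames=frames, class_names=class_names, video_id=video_id)


@pytest.fixture
def disk_sequence():
    """Static 16×16 sequence with one disk-ish structure, 5 frames."""
    frame = np.zeros((16, 16), dtype=np.int64)
    yy, xx = np.ogrid[:16, :16]
    frame[(yy - 8) ** 2 + (xx - 8) ** 2 <= 16] = 1
    return make_sequence(np.stack([frame] * 5), ["background", "disk"])
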