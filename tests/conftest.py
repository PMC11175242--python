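import numpy as np
import pytest

from vpull.keypoints import COCO_KEYPOINTS, Trajectory


def random_trajectory(rng: np.random.Generator, n: int = 60, missing: float = 0.0) -> Trajectory:
    """Random valid trajectory; optionally drop keypoints at random frames."""
    times = np.arange(n) / 30.0
    xyz = rng.normal(0.0, 1.0, (n, len(COCO_KEYPOINTS), 3))
    conf = rng.uniform(0.5, 1.0, (n, len(COCO_KEYPOINTS)))
    if missing:
        drop = rng.random((n, len(COCO_KEYPOINTS))) < missing
        xyz[drop] = np.nan
        conf[drop] = 0.0
    return Trajectory(times, xyz, conf, 30.0, {"subject_id": "synthetic"})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
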