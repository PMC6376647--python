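import numpy as np
import pytest

from stackdetect.iostack import AnnotationSet, PlaneTriplet
from stackdetect.model import ModelConfig, build_detector


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_detector():
    """Smallest useful network: depth 1, 2 base filters."""
    return build_detector(ModelConfig(depth=1, base_filters=2), rng=0)


@pytest.fixture()
def small_triplet(rng):
    channels = rng.normal(0, 1, (3, 32, 32)).astype(np.float32)
    return PlaneTriplet(channels=channels, source_plane_indices=(1, 2, 3))


def random_annotations(rng, shape=(64, 64), n=8, min_sep=0):
    """Random duplicate-free annotation set, optionally with min separation."""
    pts = []
    tries = 0
    while len(pts) < n and tries < 2000:
        tries += 1
        p = (int(rng.integers(0, shape[0])), int(rng.integers(0, shape[1])))
        if min_sep:
            if any((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < min_sep**2 for q in pts):
                continue
        if p not in pts:
            pts.append(p)
    return AnnotationSet(points=np.array(pts).reshape(len(pts), 2), image_shape=shape)
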