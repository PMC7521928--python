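import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from enspatial.frames import ImageFrame, Rect

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rect() -> Rect:
    return Rect(450.0, 450.0)


@pytest.fixture
def make_frame(rect):
    """Build a frame from (x, y, phenotype) triples."""

    def _make(cells, image_id="img0", frame_rect=None, **kwargs) -> ImageFrame:
        frame_rect = frame_rect or rect
        xs, ys, phs = zip(*cells) if cells else ((), (), ())
        return ImageFrame(
            image_id=image_id,
            rect=frame_rect,
            x=np.array(xs, dtype=float),
            y=np.array(ys, dtype=float),
            phenotype=np.array(phs, dtype=object),
            **kwargs,
        )

    return _make


@pytest.fixture
def random_frame(rect):
    """A frame of n uniformly placed cells with phenotypes drawn from labels."""

    def _make(n, labels, seed, image_id="rand0", frame_rect=None) -> ImageFrame:
        frame_rect = frame_rect or rect
        rng = np.random.default_rng(seed)
        return ImageFrame(
            image_id=image_id,
            rect=frame_rect,
            x=rng.uniform(0, frame_rect.width, n),
            y=rng.uniform(0, frame_rect.height, n),
            phenotype=rng.choice(list(labels), size=n).astype(object),
        )

    return _make
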