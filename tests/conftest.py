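import numpy as np
import pytest

from laryngoseg import phantom


@pytest.fixture(scope="session")
def default_params() -> phantom.PhantomParams:
    return phantom.PhantomParams()


@pytest.fixture(scope="session")
def default_frame(default_params) -> phantom.PhantomFrame:
    """Noise-free, axis-vertical phantom frame."""
    return phantom.generate_frame(default_params, 0)


@pytest.fixture(scope="session")
def tilted_frame() -> phantom.PhantomFrame:
    return phantom.generate_frame(
        phantom.PhantomParams(axis_angle_deg=20.0, seed=7), 0
    )


class SpyBackend:
    """Records every prompt combination it is called with."""

    deterministic = True

    def __init__(self, mask=None):
        self.calls = []
        self.mask = mask

    def __call__(self, image, points, box, mask_logits):
        self.calls.append(
            {
                "points": None if points is None else np.array(points),
                "box": box,
                "logits": None if mask_logits is None else np.array(mask_logits),
            }
        )
        mask = (
            np.zeros(np.asarray(image).shape[:2], dtype=bool)
            if self.mask is None
            else self.mask
        )
        return mask, np.where(mask, 8.0, -8.0), 0.5


@pytest.fixture
def spy_backend():
    return SpyBackend()
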