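import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from granulequant.io import AnalysisConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture()
def disc_image():
    """Noiseless bright disc (radius 25 px) on a dark background."""
    def make(radius: float = 25.0, shape=(160, 160), interior=650.0, bg=200.0,
             centre=None, blur=1.3):
        import scipy.ndimage as ndi

        img = np.full(shape, bg, dtype=float)
        r0, c0 = centre or (shape[0] // 2, shape[1] // 2)
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        img[(rr - r0) ** 2 + (cc - c0) ** 2 < radius**2] = interior
        if blur:
            img = ndi.gaussian_filter(img, blur)
        return img
    return make
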