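import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from sidmap import Peak, PeakList


@pytest.fixture
def small_list() -> PeakList:
    """Ten backbone peaks on a coarse grid, ids p01..p10."""
    peaks = [
        Peak(id=f"p{i + 1:02d}", h_ppm=7.0 + 0.3 * i, n_ppm=105.0 + 2.5 * i,
             intensity=1.0 + 0.1 * i, kind="backbone_amide")
        for i in range(10)
    ]
    return PeakList(peaks, {"label": "small"})
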