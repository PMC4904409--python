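import pytest

from soartrack.config import SimulationConfig
from soartrack.preprocess import detect_flight, smooth_vertical_speed
from soartrack.segmentation import segment_track
from soartrack.synthetic import simulate_track


@pytest.fixture(scope="session")
def small_sim():
    """Two simulated bird-days under default study conditions."""
    return simulate_track(SimulationConfig(seed=1, n_days=2))


@pytest.fixture(scope="session")
def small_segmented(small_sim):
    """The same track preprocessed and segmented (read-only in tests)."""
    series = small_sim.series
    detect_flight(series)
    smooth_vertical_speed(series)
    segments = segment_track(series)
    return small_sim, segments
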