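import numpy as np
import pytest

from apoutlier import IndexedSeries

# the five published 5-element demonstration series plus the bad-detection
# series with the interior outlier at 103.6
TABLE_SERIES = {
    1: [100, 101, 102, 103, 104],
    2: [100, 101, 102, 103, 104.01],
    3: [100, 101, 102, 103, 204],
    4: [99.99, 101, 102, 103, 104],
    5: [1, 101, 102, 103, 104],
    6: [100, 101, 102, 103.6, 104],
}


@pytest.fixture
def table_series():
    return {k: IndexedSeries.from_values(v) for k, v in TABLE_SERIES.items()}


@pytest.fixture
def interior_outlier_series():
    """Series whose only outlier (103.6) is neither the max nor the min."""
    return IndexedSeries.from_values(TABLE_SERIES[6])


def make_ap(n: int, a1: float, d: float) -> IndexedSeries:
    return IndexedSeries.from_values(a1 + d * np.arange(n))


@pytest.fixture
def ap_factory():
    return make_ap
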