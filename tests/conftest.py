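import numpy as np
import pytest

from wetlandchange.raster import Grid, HabitatMap
from wetlandchange.synthetic import two_date_scenario


LEGEND4 = {1: "a", 2: "b", 3: "c", 4: "d"}


def random_map(rng, rows=8, cols=8, class_ids=(1, 2, 3, 4), legend=None,
               grid=None, nodata_frac=0.0):
    """A random categorical map for oracle comparisons."""
    labels = rng.choice(np.array(class_ids), size=(rows, cols))
    if nodata_frac > 0:
        labels = np.where(rng.random((rows, cols)) < nodata_frac, 255, labels)
    legend = legend or {int(c): str(c) for c in class_ids}
    return HabitatMap(labels, legend, grid or Grid(rows, cols))


@pytest.fixture
def rng():
    return np.random.default_rng(20160923)


@pytest.fixture(scope="session")
def small_scenario():
    """One compact two-date synthetic scenario shared across tests."""
    return two_date_scenario(seed=7, rows=80, cols=80, n_areas_per_class=12)
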