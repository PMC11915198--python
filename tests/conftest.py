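import numpy as np
import pytest

from firestops.grids import RasterGrid
from firestops.perimeter import BurnScene, label_fire_events


def make_scene(day_of_burn, pixel_size=300.0, max_gap_days=14, year=0) -> BurnScene:
    """BurnScene from a raw day-of-burn array, labelling events on the fly."""
    dob = np.asarray(day_of_burn, dtype=int)
    fid = label_fire_events(dob, max_gap_days=max_gap_days)
    g = RasterGrid(dob, pixel_size=pixel_size, origin=(0.0, 0.0))
    return BurnScene(day_of_burn=g, fire_id=g.like(fid), year=year)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
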